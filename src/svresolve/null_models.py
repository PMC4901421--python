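"""Null models of a paired-end sequencing library.

Structural variants are detected as departures from what an unrearranged
genome would look like in the alignment: insert sizes drawn from the library
distribution, forward-reverse mate orientation, read depth and physical
coverage fluctuating around their genome-wide means.  This module builds
those baselines:

* a :class:`GenomeMask` of regions excluded from analysis (reference N-runs
  merged with user-supplied excludable BED intervals such as low-mappability
  tracks);
* a :class:`LibraryModel` for the insert-size distribution ``f_IS``, fitted
  on read pairs from copy-neutral (CN2) regions -- a single normal by
  default, or a two-component normal mixture for noisier libraries;
* a :class:`CoverageModel` for read depth ``f_RD`` and physical coverage
  ``f_PC`` per fixed-size window (default 100 bp), normal by default with a
  negative-binomial option for low-coverage, overdispersed data.

Counting conventions (fixed for determinism): a read is counted in the
window containing its leftmost aligned base; a fragment contributes to the
physical coverage of a window if the interval from its leftmost read start
to its rightmost read end spans the window midpoint.
"""

from __future__ import annotations

import json
import math
import random
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pysam
from pyfaidx import Fasta
from scipy import stats
from scipy.special import logsumexp

# Global numeric / filtering policy.
LOG_DENSITY_FLOOR = -50.0       # per-observation floor; keeps scores finite
MIN_PAIRS = 1000                # minimum proper pairs to fit f_IS
MIN_WINDOWS = 500               # minimum windows to fit f_RD / f_PC
DEFAULT_WINDOW = 100            # bp, coverage window size
DEFAULT_S = 3.0                 # insert-size aberrance multiplier (mu +- s*sigma)
MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Raised when a null model cannot be fitted or is used unfitted."""


# ---------------------------------------------------------------------------
# Genome mask
# ---------------------------------------------------------------------------

def _merge_intervals(ivals):
    out = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class GenomeMask:
    """Excluded regions per chromosome, 0-based half-open, merged and sorted."""

    intervals: dict = field(default_factory=dict)  # chrom -> list[(start, end)]

    def add(self, chrom: str, start: int, end: int) -> None:
        self.intervals.setdefault(chrom, []).append((start, end))

    def merge(self) -> "GenomeMask":
        self.intervals = {c: _merge_intervals(v) for c, v in self.intervals.items()}
        return self

    def contains(self, chrom: str, pos: int) -> bool:
        ivals = self.intervals.get(chrom)
        if not ivals:
            return False
        i = bisect_right([s for s, _ in ivals], pos) - 1
        return i >= 0 and ivals[i][0] <= pos < ivals[i][1]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.intervals.get(chrom, ()):
            if s < end and start < e:
                return True
        return False

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def _n_runs(seq: str):
    """Yield (start, end) of maximal runs of N/n in *seq*."""
    start = None
    for i, base in enumerate(seq):
        if base in "Nn":
            if start is None:
                start = i
        elif start is not None:
            yield start, i
            start = None
    if start is not None:
        yield start, len(seq)


def read_bed(path: str):
    """Minimal BED3 reader: yields (chrom, start, end)."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            yield f[0], int(f[1]), int(f[2])


def build_genome_mask(reference: str, excludable: list[str] | None = None,
                      warn=None) -> GenomeMask:
    """Union of reference N-runs and excludable BED intervals, merged.

    BED intervals on chromosomes absent from the reference are skipped with
    a warning (callable *warn*, default prints to stderr).
    """
    import sys
    if warn is None:
        warn = lambda m: print(m, file=sys.stderr)
    fa = Fasta(reference, as_raw=True, sequence_always_upper=False)
    mask = GenomeMask()
    names = set(fa.keys())
    for chrom in fa.keys():
        seq = str(fa[chrom][:])
        for s, e in _n_runs(seq):
            mask.add(chrom, s, e)
    for bed in excludable or ():
        for chrom, s, e in read_bed(bed):
            if chrom not in names:
                warn(f"mask: skipping interval on unknown chromosome {chrom!r}")
                continue
            mask.add(chrom, s, e)
    return mask.merge()


# ---------------------------------------------------------------------------
# Library (insert size) model
# ---------------------------------------------------------------------------

@dataclass
class LibraryModel:
    """Insert-size null distribution f_IS.

    ``mode == "normal"``: f_IS ~ N(mu_IS, sigma_IS^2).
    ``mode == "bimodal"``: f_IS ~ p*N(mu_IS1, sigma_IS1^2) + (1-p)*N(mu_IS2, sigma_IS2^2);
    mu_IS/sigma_IS then hold the overall mixture moments.
    ``s`` is the aberrance multiplier: inserts outside mu_IS +- s*sigma_IS are
    size-aberrant.
    """

    mode: str = "normal"
    mu_IS: float = float("nan")
    sigma_IS: float = float("nan")
    s: float = DEFAULT_S
    p: float | None = None
    mu_IS1: float | None = None
    sigma_IS1: float | None = None
    mu_IS2: float | None = None
    sigma_IS2: float | None = None

    def __post_init__(self):
        if self.mode not in ("normal", "bimodal"):
            raise ModelError(f"unknown library mode {self.mode!r}")

    @property
    def fitted(self) -> bool:
        return math.isfinite(self.mu_IS) and math.isfinite(self.sigma_IS)

    def log_density(self, value, floor: float | None = LOG_DENSITY_FLOOR):
        """Natural-log density of f_IS at *value*; floored, never -inf."""
        if not self.fitted:
            raise ModelError("library model is not fitted")
        if self.mode == "normal":
            ld = stats.norm.logpdf(value, self.mu_IS, self.sigma_IS)
        else:
            comp = np.stack([
                np.log(self.p) + stats.norm.logpdf(value, self.mu_IS1, self.sigma_IS1),
                np.log1p(-self.p) + stats.norm.logpdf(value, self.mu_IS2, self.sigma_IS2),
            ])
            ld = logsumexp(comp, axis=0)
        if floor is not None:
            ld = np.maximum(ld, floor)
        return float(ld) if np.isscalar(value) else ld

    @property
    def size_window(self) -> tuple[float, float]:
        return self.mu_IS - self.s * self.sigma_IS, self.mu_IS + self.s * self.sigma_IS


def _em_two_normal(x: np.ndarray, seed: int = 0, n_iter: int = 300,
                   tol: float = 1e-8):
    """EM fit of a two-component univariate normal mixture.

    Initialized from the empirical lower/upper halves; deterministic.
    """
    x = np.asarray(x, float)
    lo, hi = np.percentile(x, [25, 75])
    mu = np.array([lo, hi], float)
    sd = np.full(2, max(x.std(), 1e-3))
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    for _ in range(n_iter):
        logr = np.log(w)[:, None] + stats.norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        norm = logsumexp(logr, axis=0)
        r = np.exp(logr - norm)
        nk = r.sum(axis=1)
        w = nk / len(x)
        mu = (r * x).sum(axis=1) / nk
        sd = np.sqrt((r * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk)
        sd = np.maximum(sd, 1e-6)
        ll = norm.sum()
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    order = np.argsort(mu)
    return w[order], mu[order], sd[order]


def fit_library_model(alignments, neutral_regions, mode: str = "normal",
                      sample_size: int = 100000, s: float = DEFAULT_S,
                      min_pairs: int = MIN_PAIRS) -> LibraryModel:
    """Fit f_IS from proper forward-reverse pairs in copy-neutral regions.

    *alignments* is a pysam.AlignmentFile or a path; *neutral_regions* is an
    iterable of (chrom, start, end).  Duplicate/secondary/supplementary and
    MQ0 reads are ignored.  Normal mode returns the sample mean/SD of the
    observed insert lengths; bimodal mode fits a 2-component mixture by EM.
    """
    inserts = collect_insert_sizes(alignments, neutral_regions, sample_size)
    return fit_library_from_inserts(inserts, mode=mode, s=s, min_pairs=min_pairs)


def fit_library_from_inserts(inserts, mode: str = "normal", s: float = DEFAULT_S,
                             min_pairs: int = MIN_PAIRS) -> LibraryModel:
    x = np.asarray(list(inserts), float)
    if len(x) < min_pairs:
        raise ModelError(f"too few read pairs to fit insert model: {len(x)} < {min_pairs}")
    mu, sd = float(x.mean()), float(x.std())
    if sd <= 0:
        raise ModelError("degenerate insert-size sample (zero variance)")
    if mode == "normal":
        return LibraryModel("normal", mu, sd, s=s)
    w, m, v = _em_two_normal(x)
    return LibraryModel("bimodal", mu, sd, s=s, p=float(w[0]),
                        mu_IS1=float(m[0]), sigma_IS1=float(v[0]),
                        mu_IS2=float(m[1]), sigma_IS2=float(v[1]))


def _open_bam(alignments):
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, False
    return pysam.AlignmentFile(str(alignments)), True


def _use_read(read, min_mq: int = 1) -> bool:
    return not (read.is_unmapped or read.is_duplicate or read.is_secondary
                or read.is_supplementary or read.mapping_quality < min_mq)


def collect_insert_sizes(alignments, neutral_regions, sample_size=100000):
    bam, close = _open_bam(alignments)
    out = []
    try:
        for chrom, start, end in neutral_regions:
            for read in bam.fetch(chrom, start, end):
                if not _use_read(read) or read.is_reverse or read.template_length <= 0:
                    continue
                if read.mate_is_unmapped or read.reference_id != read.next_reference_id:
                    continue
                if read.mate_is_reverse:  # forward-reverse pairs only
                    out.append(read.template_length)
                if len(out) >= sample_size:
                    return out
    finally:
        if close:
            bam.close()
    return out


# ---------------------------------------------------------------------------
# Coverage model
# ---------------------------------------------------------------------------

def nb_from_moments(mu: float, var: float) -> tuple[float, float]:
    """Negative-binomial (r, p) with the given mean and variance.

    r = mu^2 / (var - mu),  p = 1 - mu / var.  Requires var > mu > 0
    (overdispersion); the scipy ``nbinom(r, 1-p)`` parameterization then has
    mean mu and variance var.
    """
    if not mu > 0:
        raise ModelError(f"mean must be positive, got {mu}")
    if not var > mu:
        raise ModelError(f"underdispersed counts (var={var} <= mu={mu}); use normal mode")
    return mu * mu / (var - mu), 1.0 - mu / var


@dataclass
class CoverageModel:
    """Read-depth (f_RD) and physical-coverage (f_PC) null distributions.

    Counts are per *window* bp (default 100).  Normal mode evaluates
    N(mu, sigma^2) densities; negative_binomial mode evaluates NB mass with
    (r, p) derived from the sample moments.
    """

    window: int = DEFAULT_WINDOW
    mode: str = "normal"
    mu_RD: float = float("nan")
    sigma_RD: float = float("nan")
    mu_PC: float = float("nan")
    sigma_PC: float = float("nan")
    r_RD: float | None = None
    p_RD: float | None = None
    r_PC: float | None = None
    p_PC: float | None = None

    def __post_init__(self):
        if self.window <= 0:
            raise ModelError("window must be positive")
        if self.mode not in ("normal", "negative_binomial"):
            raise ModelError(f"unknown coverage mode {self.mode!r}")
        if self.mode == "negative_binomial" and self.fitted and self.r_RD is None:
            self.r_RD, self.p_RD = nb_from_moments(self.mu_RD, self.sigma_RD ** 2)
            self.r_PC, self.p_PC = nb_from_moments(self.mu_PC, self.sigma_PC ** 2)

    @property
    def fitted(self) -> bool:
        return math.isfinite(self.mu_RD) and math.isfinite(self.mu_PC)

    def _log_density(self, value, mu, sigma, r, p, floor):
        if not self.fitted:
            raise ModelError("coverage model is not fitted")
        if self.mode == "normal":
            ld = stats.norm.logpdf(value, mu, sigma)
        else:
            k = np.maximum(np.rint(value), 0.0)
            ld = stats.nbinom.logpmf(k, r, 1.0 - p)
        if floor is not None:
            ld = np.maximum(ld, floor)
        return float(ld) if np.isscalar(value) else ld

    def log_density_rd(self, value, floor=LOG_DENSITY_FLOOR):
        return self._log_density(value, self.mu_RD, self.sigma_RD, self.r_RD, self.p_RD, floor)

    def log_density_pc(self, value, floor=LOG_DENSITY_FLOOR):
        return self._log_density(value, self.mu_PC, self.sigma_PC, self.r_PC, self.p_PC, floor)


def window_counts(alignments, chrom: str, start: int, end: int,
                  window: int = DEFAULT_WINDOW):
    """Per-window read-depth and physical-coverage counts over [start, end).

    RD = reads with leftmost aligned base in the window; PC = fragments whose
    [leftmost read start, rightmost read end) spans the window midpoint.
    Only full windows are used.  Returns (rd, pc) int arrays.
    """
    bam, close = _open_bam(alignments)
    try:
        n_win = (end - start) // window
        if n_win < 1:
            return np.zeros(0, int), np.zeros(0, int)
        end = start + n_win * window
        rd = np.zeros(n_win, int)
        frags = {}
        pad = 2000  # fragments anchored before `start` can still span midpoints
        for read in bam.fetch(chrom, max(0, start - pad), end + pad):
            if not _use_read(read):
                continue
            if start <= read.reference_start < end:
                rd[(read.reference_start - start) // window] += 1
            if (read.template_length > 0 and not read.mate_is_unmapped
                    and read.reference_id == read.next_reference_id):
                frags[read.query_name] = (read.reference_start,
                                          read.reference_start + read.template_length)
        mids = start + np.arange(n_win) * window + window // 2
        if frags:
            fs = np.sort(np.array([s for s, _ in frags.values()]))
            fe = np.sort(np.array([e for _, e in frags.values()]))
            # fragments with start <= mid < end
            pc = (np.searchsorted(fs, mids, "right")
                  - np.searchsorted(fe, mids, "right")).astype(int)
        else:
            pc = np.zeros(n_win, int)
        return rd, pc
    finally:
        if close:
            bam.close()


def fit_coverage_model(alignments, neutral_regions, window: int = DEFAULT_WINDOW,
                       mode: str = "normal",
                       min_windows: int = MIN_WINDOWS) -> CoverageModel:
    """Fit f_RD and f_PC moments from sliding windows over neutral regions."""
    rds, pcs = [], []
    bam, close = _open_bam(alignments)
    try:
        for chrom, start, end in neutral_regions:
            rd, pc = window_counts(bam, chrom, start, end, window)
            rds.append(rd)
            pcs.append(pc)
    finally:
        if close:
            bam.close()
    rd = np.concatenate(rds) if rds else np.zeros(0)
    pc = np.concatenate(pcs) if pcs else np.zeros(0)
    return fit_coverage_from_counts(rd, pc, window=window, mode=mode,
                                    min_windows=min_windows)


def fit_coverage_from_counts(rd, pc, window: int = DEFAULT_WINDOW,
                             mode: str = "normal",
                             min_windows: int = MIN_WINDOWS) -> CoverageModel:
    rd = np.asarray(rd, float)
    pc = np.asarray(pc, float)
    if len(rd) < max(2, min_windows):
        raise ModelError(f"too few coverage windows: {len(rd)} < {max(2, min_windows)}"
                         " (need at least 2 to estimate a standard deviation)")
    m = CoverageModel(window=window, mode="normal",
                      mu_RD=float(rd.mean()), sigma_RD=float(rd.std()),
                      mu_PC=float(pc.mean()), sigma_PC=float(pc.std()))
    if m.sigma_RD <= 0 or m.sigma_PC <= 0:
        raise ModelError("degenerate coverage sample (zero variance)")
    if mode == "negative_binomial":
        m.mode = "negative_binomial"
        m.r_RD, m.p_RD = nb_from_moments(m.mu_RD, m.sigma_RD ** 2)
        m.r_PC, m.p_PC = nb_from_moments(m.mu_PC, m.sigma_PC ** 2)
    return m


def default_neutral_regions(reference: str, mask: GenomeMask, n: int = 20,
                            length: int = 50000, seed: int = 17):
    """Random mask-free windows, a fallback CN2 set for unannotated genomes."""
    fa = Fasta(reference, as_raw=True)
    rng = random.Random(seed)
    chroms = [(c, len(fa[c])) for c in fa.keys() if len(fa[c]) > length]
    out, tries = [], 0
    while len(out) < n and tries < 50 * n and chroms:
        chrom, clen = rng.choice(chroms)
        s = rng.randrange(0, clen - length)
        if not mask.overlaps(chrom, s, s + length):
            out.append((chrom, s, s + length))
        tries += 1
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_models(path: str, lib: LibraryModel, cov: CoverageModel) -> None:
    doc = {"format_version": MODEL_FORMAT_VERSION,
           "library": {k: v for k, v in lib.__dict__.items()},
           "coverage": {k: v for k, v in cov.__dict__.items()}}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_models(path: str) -> tuple[LibraryModel, CoverageModel]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelError(f"unsupported model file version: {doc.get('format_version')}")
    return LibraryModel(**doc["library"]), CoverageModel(**doc["coverage"])
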