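"""Long-read validation of predicted structural variants by recurrence
plots.

Each long read overlapping a predicted SV is compared against both the
local reference and an altered reference implementing the predicted
structure, by sliding a k-mer window (default 10 bp) along the read and
recording every exact match position: the recurrence point set {(x, y)}.
A read drawn from the true local structure forms a single diagonal run
against the correct reference, so the summed vertical deviation from the
diagonal, S_jk = sum_i |x_i - y_i|, is small against the reference that
matches the read's provenance and large against the other.  The per-read
score S_j = S_orig / S_alt - 1 is positive when the read favours the
altered structure; the SV's validation score S_val is the fraction of
informative reads with S_j > 0, and an SV validates at S_val > 0.5
(haploid) or > 0.3 (diploid).  Highly repetitive regions inflate deviation
scores for every reference, so regions whose self-score exceeds a per-base
threshold are flagged non-assessable; SVs longer than 5 kb are validated
per breakpoint on +-500 bp flank windows instead, all of which must agree.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta

from .synthetic_benchmark import revcomp, Segment, haplotype_sequence, _segment_table, _project_read

DEFAULT_K = 10
DEFAULT_FLANK = 500
LONG_SV_SPAN = 5000
SUPPORT_LARGE = 1e6             # S_j when S_alt = 0 but S_orig > 0
SELF_SCORE_PER_BP = 100.0       # assessability threshold
HAPLOID_THRESHOLD = 0.5
DIPLOID_THRESHOLD = 0.3
MIN_WINDOW_COVER = 0.5          # reads covering less of the window are dropped


@dataclass
class LongRead:
    """A long read with the reference coordinate its alignment starts at."""

    name: str
    seq: str
    chrom: str
    ref_start: int


@dataclass
class RecurrencePoints:
    points: list            # [(x, y), ...]
    k: int = DEFAULT_K


@dataclass
class ValidationResult:
    s_val: float
    m: int                          # informative reads
    supportive: int
    validated: bool
    assessable: bool
    read_scores: list = field(default_factory=list)
    per_bp: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Altered reference construction
# ---------------------------------------------------------------------------

def apply_layout(fasta: Fasta, chrom: str, layout) -> str:
    parts = []
    for s, e, o in layout:
        seq = str(fasta[chrom][s:e])
        parts.append(seq if o == "+" else revcomp(seq))
    return "".join(parts)


def build_alt_reference(reference: str, chrom: str, region: tuple[int, int],
                        layout, flank: int = DEFAULT_FLANK):
    """Local original and altered sequences for a predicted structure.

    *layout* replaces reference [region_start, region_end) with the given
    (start, end, strand) slices; *flank* bp of unaltered sequence surround
    both versions.  Returns (original, altered, window_start).
    """
    fa = Fasta(reference, as_raw=True)
    start, end = region
    clen = len(fa[chrom])
    if not (0 <= start <= end <= clen):
        raise ValueError(f"call region {region} outside {chrom} (len {clen})")
    ws = max(0, start - flank)
    we = min(clen, end + flank)
    orig = str(fa[chrom][ws:we])
    alt = (str(fa[chrom][ws:start]) + apply_layout(fa, chrom, layout)
           + str(fa[chrom][end:we]))
    return orig, alt, ws


def call_layout(call) -> tuple[tuple[int, int], list]:
    """(region, replacement layout) implementing an SVCall's structure."""
    if call.type == "CSV" or call.allele_a or call.allele_b:
        from .rearrange import structure_from_string, reference_structure
        bps = call.bps
        n = len(bps) - 1
        ref = reference_structure(n)
        for s in (call.allele_a, call.allele_b):
            st = structure_from_string(s)
            if st != ref:
                layout = [(bps[b - 1], bps[b], "+" if o > 0 else "-")
                          for b, o in st]
                return (bps[0], bps[-1]), layout
        return (bps[0], bps[-1]), [(bps[0], bps[-1], "+")]
    s, e = call.start, call.end
    if call.type == "DEL":
        return (s, e), []
    if call.type == "INV":
        return (s, e), [(s, e, "-")]
    if call.type == "DUP_TANDEM":
        return (s, e), [(s, e, "+"), (s, e, "+")]
    raise ValueError(f"no layout rule for call type {call.type}")


# ---------------------------------------------------------------------------
# Recurrence scoring
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int):
    idx = defaultdict(list)
    for y in range(len(seq) - k + 1):
        idx[seq[y:y + k]].append(y)
    return idx


def recurrence_points(read_seq: str, reference_seq: str, k: int = DEFAULT_K,
                      band: float | None = None,
                      both_strands: bool = True) -> RecurrencePoints:
    """Exact k-mer matches of the read against the reference, as recorded
    (x = window start on the read, y = match start on the reference).

    Reverse-strand matches are included by default, as in a dot plot: an
    inverted segment then shows up as off-diagonal points rather than
    disappearing entirely.  With *band* set (e.g. 0.1), only points within
    that fractional deviation of the diagonal are kept."""
    if len(read_seq) < k:
        return RecurrencePoints([], k)
    idx = _kmer_index(reference_seq, k)
    pts = []
    L = max(len(read_seq), len(reference_seq))
    for x in range(len(read_seq) - k + 1):
        kmer = read_seq[x:x + k]
        hits = list(idx.get(kmer, ()))
        if both_strands:
            rc = revcomp(kmer)
            if rc != kmer:
                hits += idx.get(rc, ())
        for y in hits:
            if band is not None and abs(x - y) > band * L:
                continue
            pts.append((x, y))
    return RecurrencePoints(pts, k)


def deviation_score(points: RecurrencePoints) -> float:
    """S_jk = sum over matched points of |x - y|."""
    return float(sum(abs(x - y) for x, y in points.points))


def orient_read(read_seq: str, reference_seq: str, k: int = DEFAULT_K) -> str:
    """Canonicalize read orientation: keep whichever of read / reverse
    complement shares more forward-strand k-mers with the reference."""
    fwd = len(recurrence_points(read_seq, reference_seq, k,
                                both_strands=False).points)
    rc = revcomp(read_seq)
    rev = len(recurrence_points(rc, reference_seq, k,
                                both_strands=False).points)
    return read_seq if fwd >= rev else rc


def read_score(s_orig: float, s_alt: float) -> float | None:
    """S_j = S_orig / S_alt - 1; None when both scores are 0 (uninformative);
    a large positive constant when only S_alt is 0."""
    if s_orig == 0 and s_alt == 0:
        return None
    if s_alt == 0:
        return SUPPORT_LARGE
    return s_orig / s_alt - 1.0


def sv_validation_score(read_scores, ploidy: int = 2) -> ValidationResult:
    """S_val = (# reads with S_j > 0) / m over informative reads; validated
    above 0.5 (haploid) or 0.3 (diploid); m = 0 means non-assessable."""
    scores = [s for s in read_scores if s is not None]
    m = len(scores)
    if m == 0:
        return ValidationResult(float("nan"), 0, 0, False, False, [])
    supp = sum(1 for s in scores if s > 0)
    s_val = supp / m
    thr = HAPLOID_THRESHOLD if ploidy == 1 else DIPLOID_THRESHOLD
    return ValidationResult(s_val, m, supp, s_val > thr, True, scores)


def assess_region(reference_seq: str, k: int = DEFAULT_K,
                  per_bp_threshold: float = SELF_SCORE_PER_BP) -> bool:
    """Assessable unless the reference's self recurrence deviation exceeds
    *per_bp_threshold* per base (repeat-driven off-diagonal matches)."""
    if not reference_seq:
        raise ValueError("empty reference sequence")
    pts = recurrence_points(reference_seq, reference_seq, k)
    return deviation_score(pts) / len(reference_seq) <= per_bp_threshold


# ---------------------------------------------------------------------------
# SV validation drivers
# ---------------------------------------------------------------------------

def _score_reads_against(reads: list[LongRead], orig: str, alt: str,
                         window_start: int, k: int,
                         cover_window: tuple[int, int] | None = None) -> list:
    win_len = len(orig)
    cov_s, cov_len = cover_window or (window_start, win_len)
    out = []
    for rd in reads:
        clip = max(0, window_start - rd.ref_start)
        seq = rd.seq[clip:clip + win_len + 1000]
        cover = min(rd.ref_start + len(rd.seq), cov_s + cov_len) \
            - max(rd.ref_start, cov_s)
        if cover < MIN_WINDOW_COVER * cov_len or len(seq) < k:
            continue
        seq = orient_read(seq, orig, k)
        s_orig = deviation_score(recurrence_points(seq, orig, k))
        s_alt = deviation_score(recurrence_points(seq, alt, k))
        out.append(read_score(s_orig, s_alt))
    return out


def validate_sv(reference: str, chrom: str, region: tuple[int, int], layout,
                reads: list[LongRead], ploidy: int = 2, k: int = DEFAULT_K,
                flank: int = DEFAULT_FLANK) -> ValidationResult:
    """Validate one (short) SV: score every overlapping read against the
    original and altered local references."""
    orig, alt, ws = build_alt_reference(reference, chrom, region, layout, flank)
    if not assess_region(orig, k):
        return ValidationResult(float("nan"), 0, 0, False, False, [])
    scores = _score_reads_against(reads, orig, alt, ws, k)
    return sv_validation_score(scores, ploidy)


def _junction_windows(reference: str, chrom: str, layout, region,
                      flank: int = DEFAULT_FLANK):
    """Per-breakpoint windows for a long SV.

    The altered window joins *flank* bp of exiting sequence to *flank* bp
    of entering sequence; the original window spans both reference loci of
    the junction (so distal read content still registers as off-diagonal
    matches).  Yields (orig, alt, window_start, cover_window) with
    cover_window the +-flank neighbourhood of the exit locus against which
    read coverage is judged.
    """
    from .synthetic_benchmark import layout_junctions
    fa = Fasta(reference, as_raw=True)
    clen = len(fa[chrom])
    wins = []
    for exit_c, exit_d, entry_c, entry_d in layout_junctions(layout, *region):
        if exit_d == "+":
            left = str(fa[chrom][max(0, exit_c - flank):exit_c])
        else:
            left = revcomp(str(fa[chrom][exit_c:min(clen, exit_c + flank)]))
        if entry_d == "+":
            right = str(fa[chrom][entry_c:min(clen, entry_c + flank)])
        else:
            right = revcomp(str(fa[chrom][max(0, entry_c - flank):entry_c]))
        alt = left + right
        ws = max(0, min(exit_c, entry_c) - flank)
        we = min(clen, max(exit_c, entry_c) + flank)
        orig = str(fa[chrom][ws:we])
        cover_window = (max(0, exit_c - flank), 2 * flank)
        wins.append((orig, alt, ws, cover_window))
    return wins


def validate_long_sv(reference: str, chrom: str, region: tuple[int, int],
                     layout, reads: list[LongRead], ploidy: int = 2,
                     k: int = DEFAULT_K,
                     flank: int = DEFAULT_FLANK) -> ValidationResult:
    """Validate an SV longer than 5 kb breakpoint by breakpoint.

    Each novel junction is scored on its own +-*flank* bp window; the SV
    validates only if every junction window individually validates, and is
    non-assessable if any junction window is."""
    per_bp = []
    for orig, alt, ws, cover_win in _junction_windows(reference, chrom,
                                                      layout, region, flank):
        cs, cl = cover_win
        if not assess_region(orig[cs - ws:cs - ws + cl] or orig, k):
            per_bp.append(ValidationResult(float("nan"), 0, 0, False, False, []))
            continue
        scores = _score_reads_against(reads, orig, alt, ws, k,
                                      cover_window=cover_win)
        per_bp.append(sv_validation_score(scores, ploidy))
    assessable = all(r.assessable for r in per_bp) and bool(per_bp)
    validated = assessable and all(r.validated for r in per_bp)
    m = sum(r.m for r in per_bp)
    supp = sum(r.supportive for r in per_bp)
    s_val = supp / m if m else float("nan")
    return ValidationResult(s_val, m, supp, validated, assessable,
                            per_bp=per_bp)


# ---------------------------------------------------------------------------
# Synthetic long reads
# ---------------------------------------------------------------------------

def simulate_long_reads(haplotypes, reference: str, chrom: str,
                        region: tuple[int, int], n_reads: int,
                        read_len: int = 8000, seed: int = 0,
                        hap_indices=(0, 1)) -> list[LongRead]:
    """Error-free long reads drawn from haplotype sequence around *region*,
    with reference start coordinates from the segment map projection."""
    fa = Fasta(reference, as_raw=True)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_reads):
        hap_idx = hap_indices[i % len(hap_indices)]
        segs = haplotypes[hap_idx][chrom]
        seq = haplotype_sequence(segs, fa, chrom)
        offs = _segment_table(segs)
        # haplotype coordinate of the base just left of the region
        target = region[0] - 1
        hap_anchor = 0
        for hs, he, seg in offs:
            if (seg.start is not None and seg.strand == "+"
                    and seg.start <= target < seg.end):
                hap_anchor = hs + (target - seg.start)
                break
        span = region[1] - region[0]
        lo = max(0, hap_anchor - read_len + span + 500)
        hi = min(max(0, len(seq) - read_len), max(lo + 1, hap_anchor - 500))
        s = int(rng.integers(lo, hi)) if hi > lo else lo
        # alignment start = reference position of the first mapped base
        ref_start = region[0] - read_len // 2
        for hs, he, seg in offs:
            if seg.start is None or he <= s:
                continue
            if seg.strand == "+":
                ref_start = seg.start + (max(s, hs) - hs)
            else:
                ref_start = seg.start
            break
        out.append(LongRead(f"long{i}", seq[s:s + read_len], chrom, ref_start))
    return out
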