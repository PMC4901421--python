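"""Randomized iterative rearrangement of inter-breakpoint blocks.

Given a cluster of n breakpoints, the n-1 blocks between adjacent
breakpoints are rearranged on one or two alleles.  Each candidate structure
is scored against the null models: every read pair in the region is
projected onto the candidate layout (its ends relocated to the concatenated
block coordinates, orientation-adjusted through inverted blocks, and -- on a
diploid structure -- assigned to the allele that explains it better), and
the composite score

    S_j = sum_i Score_IS_ij * (1 + sum_i Score_PO_ij / n)
          + tau * sum Score_RD * (1 - sum Score_PC)

integrates insert-size log-densities, the fraction of forward-reverse
pairs, read-depth log-densities per 100 bp window and physical-coverage
log-densities per novel junction, with tau = log f_IS(mu_IS) / log
f_RD(mu_RD) bringing the two parts onto the same scale.  Read-depth and
physical-coverage terms compare observed counts to copy-number-scaled
expectations by evaluating the fitted null at (mu + observed - expected),
so a structure whose implied copy numbers and junctions explain the counts
scores at the null's mode.

The search proposes a simple rearrangement (deletion, inversion or
insertion) of each block on the active allele per iteration, selects the
next structure by softmax over candidate scores, stalls out after 100
unchanged iterations, then restarts for a second 100-iteration pass that
avoids the converged structure; the best-scoring structure seen overall is
returned.  Deterministic hill climbing and exhaustive enumeration within
copy-number bounds are provided as alternatives (the latter mainly as a
small-region oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .null_models import (CoverageModel, LibraryModel, LOG_DENSITY_FLOOR,
                          ModelError)

ORIENT_PENALTY = 1e7       # utility penalty for a non-FR candidate placement
MAX_ENUM = 200000          # brute-force enumeration cap

Oriented = tuple[int, int]          # (block id, orientation +1/-1)
Structure = tuple[Oriented, ...]    # middle part of an allele, flanks implicit


# ---------------------------------------------------------------------------
# Structure strings
# ---------------------------------------------------------------------------

def structure_to_string(structure: Structure) -> str:
    """``((1,+1),(2,-1))`` -> ``"ab^"``; empty structure -> ``"-"``."""
    if not structure:
        return "-"
    out = []
    for b, o in structure:
        out.append(chr(ord("a") + b - 1) + ("^" if o < 0 else ""))
    return "".join(out)


def structure_from_string(s: str) -> Structure:
    if s in ("-", ""):
        return ()
    out = []
    for ch in s:
        if ch == "^":
            b, _ = out[-1]
            out[-1] = (b, -1)
        else:
            out.append((ord(ch) - ord("a") + 1, +1))
    return tuple(out)


def reference_structure(n_blocks: int) -> Structure:
    return tuple((b, +1) for b in range(1, n_blocks + 1))


# ---------------------------------------------------------------------------
# Copy-number bounds
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberBounds:
    """Per-block bounds on the *total* copy count across the two alleles:
    [max(0, cn_hat - 1), cn_hat + 1] around the local-depth-derived cn_hat."""

    cn_hat: dict[int, int]

    def min(self, block: int) -> int:
        return max(0, self.cn_hat[block] - 1)

    def max(self, block: int) -> int:
        return self.cn_hat[block] + 1

    def allows(self, counts: dict[int, int]) -> bool:
        return all(self.min(b) <= counts.get(b, 0) <= self.max(b)
                   for b in self.cn_hat)


def _counts(structure: Structure, n_blocks: int) -> dict[int, int]:
    c = {b: 0 for b in range(1, n_blocks + 1)}
    for b, _ in structure:
        c[b] += 1
    return c


def diploid_counts(a: Structure, b: Structure, n_blocks: int) -> dict[int, int]:
    ca = _counts(a, n_blocks)
    cb = _counts(b, n_blocks)
    return {k: ca[k] + cb[k] for k in ca}


# ---------------------------------------------------------------------------
# Region preparation
# ---------------------------------------------------------------------------

@dataclass
class PairObs:
    """One read pair, aligned coordinates only (0-based half-open)."""

    s1: int
    e1: int
    strand1: int    # +1 forward, -1 reverse
    s2: int
    e2: int
    strand2: int


@dataclass
class RegionData:
    """A breakpoint cluster's scoring context: blocks, flanks, the read
    pairs in the region (pre-assigned to layout elements), observed
    read-depth per window, and the fitted null models."""

    chrom: str
    bps: list[int]
    flank: int
    lib: LibraryModel
    cov: CoverageModel
    ploidy: int = 2
    pairs: list = field(default_factory=list)       # (elem, off, alen, strand) x2
    obs_rd: np.ndarray = None
    win_block: np.ndarray = None                    # element id per window
    n_blocks: int = 0
    read_len: float = 100.0

    @property
    def region_start(self) -> int:
        return self.bps[0] - self.flank

    @property
    def region_end(self) -> int:
        return self.bps[-1] + self.flank

    def block_interval(self, b: int) -> tuple[int, int]:
        return self.bps[b - 1], self.bps[b]

    def element_length(self, e: int) -> int:
        if e == 0 or e == self.n_blocks + 1:
            return self.flank
        return self.bps[e] - self.bps[e - 1]


def _element_of(region: RegionData, pos: int) -> tuple[int, int]:
    """(element id, offset) of reference position *pos*; flanks extend
    linearly beyond the region so outside mates stay projectable."""
    bps = region.bps
    if pos < bps[0]:
        return 0, pos - region.region_start
    if pos >= bps[-1]:
        return region.n_blocks + 1, pos - bps[-1]
    i = int(np.searchsorted(np.asarray(bps), pos, "right"))
    return i, pos - bps[i - 1]


def prepare_region(chrom: str, bps: list[int], pairs: list[PairObs],
                   read_starts, lib: LibraryModel, cov: CoverageModel,
                   ploidy: int = 2) -> RegionData:
    """Build the scoring context for a cluster.

    *pairs* are the read pairs with any end within the region +- one flank;
    *read_starts* is a sorted array of leftmost aligned bases of all usable
    reads on the chromosome (for the observed depth per window).
    """
    if len(bps) < 2:
        raise ValueError("a cluster needs at least two breakpoints")
    flank = int(round(lib.mu_IS + 3 * lib.sigma_IS))
    w = cov.window
    flank = (flank // w) * w  # align flanks to whole windows
    region = RegionData(chrom, list(bps), flank, lib, cov, ploidy,
                        n_blocks=len(bps) - 1)
    ends = []
    for p in pairs:
        (e1, o1) = _element_of(region, (p.s1 + p.e1) // 2)
        (e2, o2) = _element_of(region, (p.s2 + p.e2) // 2)
        # offsets are of the aligned start, elements chosen by midpoint
        off1 = p.s1 - _element_start(region, e1)
        off2 = p.s2 - _element_start(region, e2)
        ends.append(((e1, off1, p.e1 - p.s1, p.strand1),
                     (e2, off2, p.e2 - p.s2, p.strand2)))
    region.pairs = ends
    n_win = (region.region_end - region.region_start) // w
    starts = np.asarray(read_starts)
    edges = region.region_start + np.arange(n_win + 1) * w
    region.obs_rd = (np.searchsorted(starts, edges[1:])
                     - np.searchsorted(starts, edges[:-1])).astype(float)
    mids = edges[:-1] + w // 2
    region.win_block = np.array([_element_of(region, m)[0] for m in mids])
    if ends:
        region.read_len = float(np.median([e[0][2] for e in ends]))
    return region


def _element_start(region: RegionData, e: int) -> int:
    if e == 0:
        return region.region_start
    if e == region.n_blocks + 1:
        return region.bps[-1]
    return region.bps[e - 1]


def estimate_cn_bounds(region: RegionData) -> CopyNumberBounds:
    """cn_hat per block = round(ploidy * mean block window depth / mu_RD);
    blocks shorter than one window default to the ploidy."""
    cn = {}
    for b in range(1, region.n_blocks + 1):
        sel = region.win_block == b
        if sel.sum() >= 1:
            cn[b] = int(round(region.ploidy * region.obs_rd[sel].mean()
                              / region.cov.mu_RD))
        else:
            cn[b] = region.ploidy
    return CopyNumberBounds(cn)


# ---------------------------------------------------------------------------
# Projection and scoring
# ---------------------------------------------------------------------------

@dataclass
class StructureScore:
    sum_is: float
    po_fraction: float
    sum_rd: float
    sum_pc: float
    tau: float
    total: float
    n: int


def _layout(region: RegionData, structure: Structure):
    """Layout elements with offsets: [(elem, orient, offset, length), ...]."""
    elems = [(0, +1)] + list(structure) + [(region.n_blocks + 1, +1)]
    out = []
    pos = 0
    for e, o in elems:
        L = region.element_length(e)
        out.append((e, o, pos, L))
        pos += L
    return out


def _occurrences(layout):
    occ = {}
    for e, o, off, L in layout:
        occ.setdefault(e, []).append((o, off, L))
    return occ


def _project_end(occs, off, alen, strand):
    """Candidate (layout position, strand) placements of one read end."""
    out = []
    for o, eoff, L in occs:
        if o > 0:
            out.append((eoff + off, strand))
        else:
            out.append((eoff + (L - off - alen), -strand))
    return out


def _score_pairs(region: RegionData, layouts):
    """Project every pair onto each allele layout, assign it to the allele
    explaining it best, and return per-pair implied inserts / orientations /
    fragments.  Unexplained pairs get is_val = NaN."""
    mu = region.lib.mu_IS
    occs = [_occurrences(lay) for lay in layouts]
    n = len(region.pairs)
    is_val = np.full(n, np.nan)
    po = np.zeros(n)
    allele = np.full(n, -1, int)
    frag = np.zeros((n, 2))
    for i, ((e1, off1, a1, st1), (e2, off2, a2, st2)) in enumerate(region.pairs):
        best = None     # (utility, allele, lo, hi, fr)
        for k, occ in enumerate(occs):
            if e1 not in occ or e2 not in occ:
                continue
            for p1, s1 in _project_end(occ[e1], off1, a1, st1):
                for p2, s2 in _project_end(occ[e2], off2, a2, st2):
                    if p1 <= p2:
                        lo, hi = p1, max(p1 + a1, p2 + a2)
                        fr = s1 > 0 and s2 < 0
                    else:
                        lo, hi = p2, max(p1 + a1, p2 + a2)
                        fr = s2 > 0 and s1 < 0
                    util = -abs((hi - lo) - mu) - (0.0 if fr else ORIENT_PENALTY)
                    if best is None or util > best[0]:
                        best = (util, k, lo, hi, fr)
        if best is not None:
            _, k, lo, hi, fr = best
            allele[i] = k
            is_val[i] = hi - lo
            po[i] = 1.0 if fr else 0.0
            frag[i] = (lo, hi)
    return is_val, po, allele, frag


def project_reads(region: RegionData, allele_a: Structure,
                  allele_b: Structure):
    """Project every region pair onto a diploid structure.

    Returns (implied_insert, implied_fr, assigned_allele, fragment) arrays:
    implied_insert is NaN and assigned_allele -1 for pairs unexplained on
    both alleles; fragment holds the projected [start, end) interval.
    """
    layouts = [_layout(region, allele_a), _layout(region, allele_b)]
    return _score_pairs(region, layouts)


def _novel_junctions(layout, n_blocks):
    """Novel adjacencies in a layout: [(key, boundary offset), ...]."""
    out = []
    for (e1, o1, off1, L1), (e2, o2, off2, L2) in zip(layout, layout[1:]):
        if o1 > 0 and o2 > 0 and e2 == e1 + 1:
            continue
        out.append(((e1, o1, e2, o2), off2))
    return out


def score_structure(region: RegionData, allele_a: Structure,
                    allele_b: Structure) -> StructureScore:
    """Composite score S_j of a diploid structure (see module docstring)."""
    n = len(region.pairs)
    if n == 0:
        raise ModelError("no read pairs in region")
    lib, cov = region.lib, region.cov
    layouts = [_layout(region, allele_a), _layout(region, allele_b)]
    is_val, po, allele, frag = _score_pairs(region, layouts)

    explained = ~np.isnan(is_val)
    is_scores = np.full(n, LOG_DENSITY_FLOOR)
    if explained.any():
        is_scores[explained] = lib.log_density(is_val[explained])
    sum_is = float(is_scores.sum())
    po_fraction = float(po.sum()) / n

    # read depth: observed reference-window counts vs copy-number expectation
    cnt = diploid_counts(allele_a, allele_b, region.n_blocks)
    cn_win = np.array([cnt.get(b, region.ploidy) for b in region.win_block], float)
    expected = cov.mu_RD * cn_win / region.ploidy
    rd_vals = cov.mu_RD + region.obs_rd - expected
    sum_rd = float(cov.log_density_rd(rd_vals).sum())

    # physical coverage through novel junctions
    juncs = {}
    for k, lay in enumerate(layouts):
        for key, off in _novel_junctions(lay, region.n_blocks):
            juncs.setdefault(key, []).append((k, off))
    # reads straddling a novel junction are clipped there, so the fragment
    # interval abuts rather than spans it; discount the expectation by the
    # average such loss
    span_keep = max(0.5, 1.0 - region.read_len / lib.mu_IS)
    sum_pc = 0.0
    for key, sites in juncs.items():
        mult = len(sites)
        exp_pc = cov.mu_PC * span_keep * mult / region.ploidy
        spanned = np.zeros(n, bool)
        for k, off in sites:
            spanned |= (allele == k) & (frag[:, 0] < off) & (frag[:, 1] > off)
        obs = float(spanned.sum())
        sum_pc += cov.log_density_pc(cov.mu_PC + obs - exp_pc)

    tau = (lib.log_density(lib.mu_IS, floor=None)
           / cov.log_density_rd(cov.mu_RD, floor=None))
    total = sum_is * (1.0 + po_fraction) + tau * sum_rd * (1.0 - sum_pc)
    return StructureScore(sum_is, po_fraction, sum_rd, sum_pc, tau, total, n)


# ---------------------------------------------------------------------------
# Moves and selection
# ---------------------------------------------------------------------------

def propose_move(structure: Structure, n_blocks: int, rng: np.random.Generator,
                 bounds: CopyNumberBounds | None = None,
                 other_counts: dict[int, int] | None = None,
                 max_retries: int = 20) -> Structure:
    """One random simple rearrangement (deletion, inversion or insertion);
    proposals violating the copy-number bounds are resampled, then identity."""
    for _ in range(max_retries):
        move = rng.integers(0, 3)
        cand = None
        if move == 0 and structure:            # deletion
            i = int(rng.integers(0, len(structure)))
            cand = structure[:i] + structure[i + 1:]
        elif move == 1 and structure:          # inversion
            i = int(rng.integers(0, len(structure)))
            b, o = structure[i]
            cand = structure[:i] + ((b, -o),) + structure[i + 1:]
        elif move == 2:                        # insertion
            b = int(rng.integers(1, n_blocks + 1))
            o = +1 if rng.random() < 0.5 else -1
            i = int(rng.integers(0, len(structure) + 1))
            cand = structure[:i] + ((b, o),) + structure[i:]
        if cand is None:
            continue
        if bounds is not None:
            tot = _counts(cand, n_blocks)
            if other_counts:
                tot = {k: tot[k] + other_counts.get(k, 0) for k in tot}
            if not bounds.allows(tot):
                continue
        return cand
    return structure


SOFTMAX_SCALE = 0.05    # softmax unit = this fraction of the best |score|


def select_next(scores, rng: np.random.Generator, temperature: float = 1.0) -> int:
    """Softmax draw over candidate scores; higher scores more likely but not
    assured.

    The composite score is a sum over reads and windows, so its magnitude
    grows with region size; a fixed-unit softmax would degenerate to argmax.
    Scores are therefore scaled by a fraction of the best candidate's
    magnitude, making selection pressure scale-free: a candidate a few
    percent worse retains appreciable probability at temperature 1.
    """
    s = np.asarray(scores, float)
    scale = max(temperature, 1e-12) * max(1.0, SOFTMAX_SCALE * abs(s.max()))
    z = (s - s.max()) / scale
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(len(s), p=p))


# ---------------------------------------------------------------------------
# Searches
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    allele_a: Structure
    allele_b: Structure
    score: StructureScore
    iterations: int = 0
    trace: list = None

    @property
    def strings(self) -> tuple[str, str]:
        return structure_to_string(self.allele_a), structure_to_string(self.allele_b)


class _Scorer:
    """Memoized diploid scorer; canonicalizes the unordered allele pair."""

    def __init__(self, region: RegionData):
        self.region = region
        self.cache: dict = {}

    def key(self, a: Structure, b: Structure):
        return (a, b) if a <= b else (b, a)

    def __call__(self, a: Structure, b: Structure) -> StructureScore:
        k = self.key(a, b)
        if k not in self.cache:
            self.cache[k] = score_structure(self.region, a, b)
        return self.cache[k]


def _mode_setup(mode: str, n_blocks: int):
    ref = reference_structure(n_blocks)
    if mode not in ("diploid", "heterozygous", "homozygous"):
        raise ValueError(f"unknown search mode {mode!r}")
    return ref


def _diploid_of(mode: str, active: Structure, other: Structure, ref: Structure):
    if mode == "homozygous":
        return active, active
    if mode == "heterozygous":
        return active, ref
    return active, other


def run_search(region: RegionData, bounds: CopyNumberBounds | None = None,
               mode: str = "diploid", stall: int = 100, max_iter: int = 100000,
               seed: int = 0, temperature: float = 1.0,
               trace: list | None = None) -> SearchResult:
    """Two-pass randomized iterative search.

    Per iteration, one randomly chosen simple-rearrangement type is applied
    at every block position of the active allele; the scored candidate set
    (plus the unchanged structure) feeds a softmax selection.  In diploid
    mode the active allele alternates.  Terminates after *stall* unchanged
    iterations or *max_iter*; a second pass of *stall* iterations restarts
    from the reference while avoiding the converged structure; the best
    structure seen overall is returned.  Deterministic given (seed, inputs).
    """
    rng = np.random.default_rng(seed)
    n_blocks = region.n_blocks
    ref = _mode_setup(mode, n_blocks)
    if bounds is None:
        bounds = estimate_cn_bounds(region)
    scorer = _Scorer(region)

    def counts_other(active_is_a, a, b):
        if mode == "homozygous":
            return None  # handled by doubling in candidate filter
        other = b if active_is_a else a
        return _counts(other, n_blocks)

    def total_ok(cand: Structure, active_is_a: bool, a, b) -> bool:
        c = _counts(cand, n_blocks)
        if mode == "homozygous":
            tot = {k: 2 * v for k, v in c.items()}
        else:
            oc = counts_other(active_is_a, a, b)
            tot = {k: c[k] + oc.get(k, 0) for k in c}
        return bounds.allows(tot)

    def candidates_for(cur: Structure, active_is_a, a, b, avoid=None):
        move = int(rng.integers(0, 3))
        cands = []
        if move == 0:
            cands = [cur[:i] + cur[i + 1:] for i in range(len(cur))]
        elif move == 1:
            cands = [cur[:i] + ((cur[i][0], -cur[i][1]),) + cur[i + 1:]
                     for i in range(len(cur))]
        else:
            for blk in range(1, n_blocks + 1):
                o = +1 if rng.random() < 0.5 else -1
                i = int(rng.integers(0, len(cur) + 1))
                cands.append(cur[:i] + ((blk, o),) + cur[i:])
        def diploid_key(cand):
            da, db = _diploid_of(mode, cand, (b if active_is_a else a), ref)
            if not active_is_a and mode == "diploid":
                da, db = a, cand
            return scorer.key(da, db)

        out = []
        if avoid is None or diploid_key(cur) != avoid:
            out.append(cur)
        for cand in cands:
            if cand == cur or not total_ok(cand, active_is_a, a, b):
                continue
            if avoid is not None and diploid_key(cand) == avoid:
                continue
            out.append(cand)
        return out or [cur]

    def run_pass(n_iter, a, b, avoid=None, stall_limit=None):
        nonlocal best
        stalled = 0     # iterations without improving the best structure
        it = 0
        while it < n_iter:
            active_is_a = (mode != "diploid") or (it % 2 == 0)
            cur = a if active_is_a else b
            cands = candidates_for(cur, active_is_a, a, b, avoid)
            scored = []
            for cand in cands:
                if mode == "diploid":
                    da, db = (cand, b) if active_is_a else (a, cand)
                else:
                    da, db = _diploid_of(mode, cand, None, ref)
                scored.append(scorer(da, db).total)
            pick = select_next(scored, rng, temperature)
            new = cands[pick]
            if trace is not None:
                trace.append((it, structure_to_string(new), scored[pick]))
            if active_is_a:
                a = new
            else:
                b = new
            da, db = _diploid_of(mode, a, b, ref) if mode != "diploid" else (a, b)
            sc = scorer(da, db)
            if best is None or sc.total > best[2].total:
                best = (da, db, sc)
                stalled = 0
            else:
                stalled += 1
            if stall_limit is not None and stalled >= stall_limit:
                break
            it += 1
        return a, b, it

    best = None
    a = b = ref
    sc0 = scorer(*_diploid_of(mode, ref, ref, ref))
    best = (*_diploid_of(mode, ref, ref, ref), sc0)
    a, b, it1 = run_pass(max_iter, a, b, stall_limit=stall)
    fixed = scorer.key(best[0], best[1])    # pass-1 converged structure
    a2, b2, it2 = run_pass(stall, ref, ref, avoid=fixed)
    da, db, sc = best
    return SearchResult(da, db, sc, iterations=it1 + it2, trace=trace)


def hill_climb_search(region: RegionData, bounds: CopyNumberBounds | None = None,
                      mode: str = "diploid", max_steps: int = 1000) -> SearchResult:
    """Deterministic greedy search: adopt the best-scoring single-move
    neighbor (over both alleles, all move types, all positions and
    orientations) until a local optimum."""
    n_blocks = region.n_blocks
    ref = _mode_setup(mode, n_blocks)
    if bounds is None:
        bounds = estimate_cn_bounds(region)
    scorer = _Scorer(region)

    def neighbors(structure: Structure):
        out = set()
        for i in range(len(structure)):
            out.add(structure[:i] + structure[i + 1:])
            b, o = structure[i]
            out.add(structure[:i] + ((b, -o),) + structure[i + 1:])
        for blk in range(1, n_blocks + 1):
            for o in (+1, -1):
                for i in range(len(structure) + 1):
                    out.add(structure[:i] + ((blk, o),) + structure[i:])
        out.discard(structure)
        return out

    def ok(a, b):
        return bounds.allows(diploid_counts(a, b, n_blocks))

    a = b = ref
    cur = _diploid_of(mode, a, b, ref)
    cur_score = scorer(*cur)
    for _ in range(max_steps):
        best_cand, best_score = None, cur_score
        actives = (0, 1) if mode == "diploid" else (0,)
        for which in actives:
            base = a if which == 0 else b
            for nb in neighbors(base):
                if mode == "diploid":
                    da, db = (nb, b) if which == 0 else (a, nb)
                else:
                    da, db = _diploid_of(mode, nb, None, ref)
                if not ok(da, db):
                    continue
                sc = scorer(da, db)
                if sc.total > best_score.total:
                    best_cand, best_score = (da, db), sc
        if best_cand is None:
            break
        (a, b), cur_score = best_cand, best_score
        if mode == "heterozygous":
            b = ref
        elif mode == "homozygous":
            b = a
    da, db = _diploid_of(mode, a, b, ref) if mode != "diploid" else (a, b)
    return SearchResult(da, db, cur_score)


def enumerate_structures(n_blocks: int, max_count: dict[int, int],
                         cap: int = MAX_ENUM):
    """All oriented block sequences with per-block copy counts <= max_count."""
    out = []

    def extend(seq, counts):
        if len(out) > cap:
            raise ModelError(f"enumeration exceeds cap ({cap})")
        out.append(tuple(seq))
        for b in range(1, n_blocks + 1):
            if counts[b] >= max_count[b]:
                continue
            for o in (+1, -1):
                seq.append((b, o))
                counts[b] += 1
                extend(seq, counts)
                counts[b] -= 1
                seq.pop()

    extend([], {b: 0 for b in range(1, n_blocks + 1)})
    return out


def brute_force_search(region: RegionData, bounds: CopyNumberBounds | None = None,
                       mode: str = "heterozygous",
                       cap: int = MAX_ENUM) -> SearchResult:
    """Global score maximum by exhaustive enumeration within CN bounds.

    Intended as an oracle on small clusters; refuses when the enumeration
    exceeds *cap*.  In diploid mode, unordered pairs of allele structures
    are enumerated.
    """
    n_blocks = region.n_blocks
    ref = _mode_setup(mode, n_blocks)
    if bounds is None:
        bounds = estimate_cn_bounds(region)
    scorer = _Scorer(region)
    if mode == "homozygous":
        per = {b: bounds.max(b) // 2 for b in range(1, n_blocks + 1)}
    elif mode == "heterozygous":
        per = {b: max(0, bounds.max(b) - 1) for b in range(1, n_blocks + 1)}
    else:
        per = {b: bounds.max(b) for b in range(1, n_blocks + 1)}
    alleles = enumerate_structures(n_blocks, per, cap)
    best = None
    if mode == "diploid":
        seen = 0
        for i, a in enumerate(alleles):
            for b in alleles[i:]:
                if not bounds.allows(diploid_counts(a, b, n_blocks)):
                    continue
                seen += 1
                if seen > cap:
                    raise ModelError(f"enumeration exceeds cap ({cap})")
                sc = scorer(a, b)
                if best is None or sc.total > best[2].total:
                    best = (a, b, sc)
    else:
        for a in alleles:
            da, db = _diploid_of(mode, a, None, ref)
            if not bounds.allows(diploid_counts(da, db, n_blocks)):
                continue
            sc = scorer(da, db)
            if best is None or sc.total > best[2].total:
                best = (da, db, sc)
    if best is None:
        raise ModelError("no structure satisfies the copy-number bounds")
    return SearchResult(*best)
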