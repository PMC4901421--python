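"""Detection and clustering of putative breakpoints.

Aberrant read pairs betray the presence of a breakpoint nearby: pairs whose
insert length falls outside mu_IS +- s*sigma_IS, pairs without
forward-reverse orientation, and reads with a high-quality soft-clipped
portion (>= 10 % of the read at mean base quality >= 20) whose clip
position marks the junction precisely.  Discordant pairs of the same
orientation within mu_IS + 2*sigma_IS of each other are clustered;
collated split-read clip positions inside the cluster's directional window
yield the breakpoint coordinate (falling back to the rightmost end of a
forward cluster / leftmost start of a reverse cluster), and a breakpoint is
kept only if split reads exceed 20 % of the local read depth or all
aberrant reads exceed 30 %.  Breakpoints are then paired through the mates
of their supporting reads, nearby pairs (< 1 kb) are grouped, and the
connected components become breakpoint clusters whose adjacent-breakpoint
blocks feed the rearrangement search.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pysam

from .null_models import GenomeMask, LibraryModel, _use_read

DEFAULT_MAX_BPS = 8         # cap on breakpoints per cluster before subgrouping
LINK_DISTANCE = 1000        # bp; breakpoint pairs closer than this are grouped
DEDUP_TOLERANCE = 10        # bp; near-identical candidate breakpoints merge
SPLIT_FRACTION = 0.20       # split reads must exceed this fraction of RD ...
ABERRANT_FRACTION = 0.30    # ... or all aberrant reads this fraction
MIN_CLIP_QUAL = 20.0
MIN_CLIP_FRAC = 0.10


# ---------------------------------------------------------------------------
# Read-pair classification
# ---------------------------------------------------------------------------

@dataclass
class ReadPairObservation:
    """Coordinates and quality summaries of one aligned pair (0-based
    half-open; left = leftmost read on the reference)."""

    chrom: str
    left_start: int
    left_end: int
    left_strand: int            # +1 forward / -1 reverse
    right_start: int
    right_end: int
    right_strand: int
    insert: int                 # outer distance
    clip_len: tuple[int, int] = (0, 0)
    clip_qual: tuple[float, float] = (0.0, 0.0)
    read_len: tuple[int, int] = (0, 0)
    mapq: tuple[int, int] = (60, 60)


@dataclass(frozen=True)
class AberrantFlags:
    size_aberrant: bool
    orientation_aberrant: bool
    clipped: bool

    @property
    def any(self) -> bool:
        return self.size_aberrant or self.orientation_aberrant or self.clipped


def classify_read_pair(rp: ReadPairObservation, lib: LibraryModel,
                       min_clip_qual: float = MIN_CLIP_QUAL,
                       min_clip_frac: float = MIN_CLIP_FRAC) -> AberrantFlags:
    """Pure predicate implementing the three aberrance rules."""
    lo, hi = lib.size_window
    size_ab = not (lo <= rp.insert <= hi)
    orient_ab = not (rp.left_strand > 0 and rp.right_strand < 0)
    clipped = any(
        rl > 0 and cl / rl >= min_clip_frac and cq >= min_clip_qual
        for cl, cq, rl in zip(rp.clip_len, rp.clip_qual, rp.read_len))
    return AberrantFlags(size_ab, orient_ab, clipped)


# ---------------------------------------------------------------------------
# Evidence collection
# ---------------------------------------------------------------------------

@dataclass
class Anchor:
    """One read of a discordant pair."""

    start: int
    end: int
    strand: int
    pair_id: int


@dataclass
class ClipEvidence:
    pos: int
    side: str       # 'L': clipped at aligned start, 'R': at aligned end


@dataclass
class ChromEvidence:
    chrom: str
    read_len: int
    starts: np.ndarray = None           # sorted leftmost aligned bases
    anchors: list = field(default_factory=list)
    clips: list = field(default_factory=list)


def _clip_ok(read, min_frac=MIN_CLIP_FRAC, min_qual=MIN_CLIP_QUAL):
    """Yield high-quality clip evidence for one read."""
    cig = read.cigartuples
    if not cig:
        return
    quals = read.query_qualities
    rl = read.query_length or read.infer_query_length() or 0
    if rl == 0:
        return
    if cig[0][0] == 4:  # leading soft clip
        cl = cig[0][1]
        if cl / rl >= min_frac and quals is not None:
            q = float(np.mean(quals[:cl]))
            if q >= min_qual:
                yield ClipEvidence(read.reference_start, "L")
    if cig[-1][0] == 4:
        cl = cig[-1][1]
        if cl / rl >= min_frac and quals is not None:
            q = float(np.mean(quals[-cl:]))
            if q >= min_qual:
                yield ClipEvidence(read.reference_end, "R")


def collect_evidence(alignments, chrom: str, lib: LibraryModel,
                     min_mq: int = 1) -> ChromEvidence:
    """Single pass over one chromosome: depth starts, discordant-pair
    anchors, and high-quality clip positions."""
    own = not isinstance(alignments, pysam.AlignmentFile)
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    lo, hi = lib.size_window
    ev = ChromEvidence(chrom, 0)
    starts = []
    pair_ids: dict[str, int] = {}
    try:
        for read in bam.fetch(chrom):
            if not _use_read(read, min_mq):
                continue
            starts.append(read.reference_start)
            ev.read_len = max(ev.read_len, read.query_length or 0)
            ev.clips.extend(_clip_ok(read))
            if read.mate_is_unmapped or read.reference_id != read.next_reference_id:
                continue
            # pair-level aberrance, evaluated from this read's view
            isize = abs(read.template_length)
            strand = -1 if read.is_reverse else +1
            mstrand = -1 if read.mate_is_reverse else +1
            if read.reference_start <= read.next_reference_start:
                fr = strand > 0 and mstrand < 0
            else:
                fr = mstrand > 0 and strand < 0
            size_ab = isize > 0 and not (lo <= isize <= hi)
            if not (size_ab or not fr):
                continue
            pid = pair_ids.setdefault(read.query_name, len(pair_ids))
            ev.anchors.append(Anchor(read.reference_start, read.reference_end,
                                     strand, pid))
    finally:
        if own:
            bam.close()
    ev.starts = np.sort(np.asarray(starts, dtype=np.int64))
    return ev


def local_depth(ev: ChromEvidence, pos: int, window: int = 100) -> float:
    """Per-base read depth around *pos* from window start counts."""
    lo = np.searchsorted(ev.starts, pos - window // 2)
    hi = np.searchsorted(ev.starts, pos + window // 2)
    return float(hi - lo) * ev.read_len / window


# ---------------------------------------------------------------------------
# Clustering and breakpoint assignment
# ---------------------------------------------------------------------------

@dataclass
class DiscordantCluster:
    strand: int
    anchors: list

    @property
    def start(self) -> int:
        return min(a.start for a in self.anchors)

    @property
    def end(self) -> int:
        return max(a.end for a in self.anchors)

    @property
    def pair_ids(self) -> set:
        return {a.pair_id for a in self.anchors}


def cluster_discordant(anchors: list[Anchor], lib: LibraryModel):
    """Single-linkage clusters of same-orientation anchors whose consecutive
    start positions differ by at most mu_IS + 2*sigma_IS."""
    window = lib.mu_IS + 2 * lib.sigma_IS
    out = []
    for strand in (+1, -1):
        sel = sorted((a for a in anchors if a.strand == strand),
                     key=lambda a: a.start)
        cur = []
        for a in sel:
            if cur and a.start - cur[-1].start > window:
                out.append(DiscordantCluster(strand, cur))
                cur = []
            cur.append(a)
        if cur:
            out.append(DiscordantCluster(strand, cur))
    out.sort(key=lambda c: c.start)
    return out


@dataclass
class BreakpointCandidate:
    chrom: str
    position: int
    direction: int              # +1 forward cluster, -1 reverse cluster
    split_support: int
    pair_support: int
    local_rd: float
    pair_ids: set = field(default_factory=set)


def assign_breakpoint(cluster: DiscordantCluster, clips: list[ClipEvidence],
                      ev: ChromEvidence, lib: LibraryModel,
                      chrom: str | None = None) -> list[BreakpointCandidate]:
    """Breakpoints supported by one discordant cluster.

    Split reads inside the cluster's directional window (to the right of a
    forward cluster, mirrored for reverse) are collated; every clip position
    whose split support alone passes the 20 %-of-RD rule is emitted, led by
    the modal position; with no splits, the cluster-extreme position is used
    if all aberrant reads exceed 30 % of RD.
    """
    chrom = chrom or ev.chrom
    window = lib.mu_IS + 2 * lib.sigma_IS
    if cluster.strand > 0:
        lo, hi = cluster.start, cluster.end + window
        side = "R"
    else:
        lo, hi = cluster.start - window, cluster.end
        side = "L"
    positions = [c.pos for c in clips if c.side == side and lo <= c.pos <= hi]
    n_pairs = len(cluster.pair_ids)
    out = []
    if positions:
        counts = Counter(positions)
        # modal position first, ties to the leftmost
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        n_splits = len(positions)
        for rank, (pos, cnt) in enumerate(ordered):
            rd = max(local_depth(ev, pos), 1e-9)
            modal = rank == 0
            strong = cnt > SPLIT_FRACTION * rd
            passes = (n_splits > SPLIT_FRACTION * rd
                      or n_splits + n_pairs > ABERRANT_FRACTION * rd)
            if (modal and passes) or strong:
                out.append(BreakpointCandidate(chrom, pos, cluster.strand,
                                               cnt, n_pairs, rd,
                                               set(cluster.pair_ids)))
    else:
        pos = cluster.end if cluster.strand > 0 else cluster.start
        rd = max(local_depth(ev, pos), 1e-9)
        if n_pairs > ABERRANT_FRACTION * rd:
            out.append(BreakpointCandidate(chrom, pos, cluster.strand,
                                           0, n_pairs, rd,
                                           set(cluster.pair_ids)))
    return out


def dedup_candidates(candidates: list[BreakpointCandidate],
                     tol: int = DEDUP_TOLERANCE):
    """Merge candidates within *tol* bp, keeping the best-supported
    position and pooling supporting pairs."""
    out = []
    for c in sorted(candidates, key=lambda c: c.position):
        if out and c.position - out[-1].position <= tol:
            keep = out[-1]
            if c.split_support > keep.split_support:
                keep.position = c.position
                keep.direction = c.direction
            keep.split_support += c.split_support
            keep.pair_support += c.pair_support
            keep.pair_ids |= c.pair_ids
        else:
            out.append(BreakpointCandidate(c.chrom, c.position, c.direction,
                                           c.split_support, c.pair_support,
                                           c.local_rd, set(c.pair_ids)))
    return out


@dataclass
class BreakpointCluster:
    """n linked breakpoints defining n-1 blocks on one chromosome."""

    chrom: str
    positions: list[int]

    def __post_init__(self):
        self.positions = sorted(set(self.positions))
        if len(self.positions) < 2:
            raise ValueError("a breakpoint cluster needs >= 2 breakpoints")

    @property
    def blocks(self) -> list[tuple[int, int]]:
        return list(zip(self.positions, self.positions[1:]))

    @property
    def span(self) -> tuple[int, int]:
        return self.positions[0], self.positions[-1]


def link_breakpoints(candidates: list[BreakpointCandidate],
                     link_distance: int = LINK_DISTANCE):
    """Group breakpoints into clusters.

    Edges join candidates sharing a supporting read pair (mate-defined
    pairs) and candidates closer than *link_distance*; connected components
    with >= 2 breakpoints become clusters, isolated candidates are dropped.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    by_pair = defaultdict(list)
    for i, c in enumerate(candidates):
        for pid in c.pair_ids:
            by_pair[pid].append(i)
    for idxs in by_pair.values():
        for j in idxs[1:]:
            union(idxs[0], j)
    order = sorted(range(n), key=lambda i: candidates[i].position)
    for i, j in zip(order, order[1:]):
        if (candidates[j].position - candidates[i].position) < link_distance:
            union(i, j)
    comps = defaultdict(list)
    for i in range(n):
        comps[find(i)].append(i)
    clusters = []
    for idxs in comps.values():
        if len(idxs) < 2:
            continue
        chrom = candidates[idxs[0]].chrom
        clusters.append(BreakpointCluster(chrom,
                                          [candidates[i].position for i in idxs]))
    clusters.sort(key=lambda c: c.positions[0])
    return clusters


def subgroup_cluster(cluster: BreakpointCluster, max_bps: int = DEFAULT_MAX_BPS):
    """Split an oversized cluster at its widest adjacent-breakpoint gaps
    (ties broken toward the most central gap) until every subgroup has
    <= *max_bps* breakpoints; subgroups preserve breakpoint order."""
    pos = cluster.positions
    if len(pos) <= max_bps:
        return [cluster]
    gaps = np.diff(pos)
    widest = gaps.max()
    tied = np.flatnonzero(gaps == widest)
    mid = (len(pos) - 1) / 2
    cut = int(tied[np.argmin(np.abs(tied + 0.5 - mid))]) + 1
    left = BreakpointCluster(cluster.chrom, pos[:cut])
    right = BreakpointCluster(cluster.chrom, pos[cut:])
    return (subgroup_cluster(left, max_bps) + subgroup_cluster(right, max_bps))


def dump_clusters(clusters, bed_path: str, table_path: str | None = None,
                  candidates=None) -> None:
    """Debug dump: clusters as BED spans, candidates as a support table."""
    with open(bed_path, "w") as fh:
        for c in clusters:
            name = ",".join(str(p) for p in c.positions)
            fh.write(f"{c.chrom}\t{c.span[0]}\t{c.span[1]}\t{name}\n")
    if table_path is not None:
        with open(table_path, "w") as fh:
            fh.write("#chrom\tposition\tdirection\tsplit_support\t"
                     "pair_support\tlocal_rd\n")
            for c in candidates or ():
                d = "+" if c.direction > 0 else "-"
                fh.write(f"{c.chrom}\t{c.position}\t{d}\t{c.split_support}\t"
                         f"{c.pair_support}\t{c.local_rd:.2f}\n")


def detect_breakpoint_clusters(alignments, chrom: str, lib: LibraryModel,
                               mask: GenomeMask | None = None,
                               max_bps: int = 8):
    """End-to-end breakpoint discovery on one chromosome: evidence scan,
    orientation-wise clustering, breakpoint assignment with support
    thresholds, mask filtering, deduplication, mate/proximity linking and
    subgrouping.  Returns (clusters, evidence)."""
    ev = collect_evidence(alignments, chrom, lib)
    cands = []
    for cl in cluster_discordant(ev.anchors, lib):
        cands.extend(assign_breakpoint(cl, ev.clips, ev, lib, chrom))
    if mask is not None:
        cands = [c for c in cands if not mask.contains(chrom, c.position)]
    cands = dedup_candidates(cands)
    clusters = []
    for cluster in link_breakpoints(cands):
        clusters.extend(subgroup_cluster(cluster, max_bps))
    return clusters, ev
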