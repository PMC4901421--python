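"""End-to-end plumbing: null-model fitting, breakpoint discovery, the
rearrangement search and call interpretation, chained over a BAM."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from . import breakpoints as bp
from . import null_models as nm
from . import rearrange as ra
from .interpret import SVCall, classify_structure

MAX_BLOCK_LEN = 50000   # clusters with longer blocks are left unresolved


def fit_null_models(bam: str, reference: str, excludable=None,
                    neutral_regions=None, lib_mode: str = "normal",
                    cov_mode: str = "normal", window: int = 100,
                    seed: int = 17):
    """Mask construction plus library and coverage model fits.

    Without an explicit CN2 BED, random mask-free windows stand in for
    copy-neutral regions.
    """
    mask = nm.build_genome_mask(reference, excludable)
    if neutral_regions is None:
        neutral_regions = nm.default_neutral_regions(reference, mask, seed=seed)
    lib = nm.fit_library_model(bam, neutral_regions, mode=lib_mode)
    cov = nm.fit_coverage_model(bam, neutral_regions, window=window, mode=cov_mode)
    return lib, cov, mask


def extract_region_pairs(alignments, chrom: str, start: int, end: int,
                         min_mq: int = 1) -> list[ra.PairObs]:
    """Read pairs with any end aligned in [start, end).

    Mates outside the fetch window are reconstructed from the mate fields
    (approximating the mate's aligned length by this read's).
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    reads: dict[str, list] = {}
    try:
        for read in bam.fetch(chrom, max(0, start), end):
            if not nm._use_read(read, min_mq):
                continue
            if read.mate_is_unmapped or read.reference_id != read.next_reference_id:
                continue
            rec = (read.reference_start, read.reference_end,
                   -1 if read.is_reverse else +1,
                   read.next_reference_start,
                   -1 if read.mate_is_reverse else +1,
                   read.reference_end - read.reference_start)
            reads.setdefault(read.query_name, []).append(rec)
    finally:
        if own:
            bam.close()
    pairs = []
    for recs in reads.values():
        if len(recs) >= 2:
            (s1, e1, st1, *_), (s2, e2, st2, *_) = recs[0], recs[1]
        else:
            s1, e1, st1, ms, mstr, alen = recs[0]
            s2, e2, st2 = ms, ms + alen, mstr
        if s2 < s1 or (s2 == s1 and e2 < e1):
            (s1, e1, st1), (s2, e2, st2) = (s2, e2, st2), (s1, e1, st1)
        pairs.append(ra.PairObs(s1, e1, st1, s2, e2, st2))
    pairs.sort(key=lambda p: (p.s1, p.s2))
    return pairs


@dataclass
class ClusterResult:
    cluster: bp.BreakpointCluster
    result: ra.SearchResult
    calls: list = field(default_factory=list)


def resolve_cluster(alignments, cluster: bp.BreakpointCluster,
                    ev: bp.ChromEvidence, lib, cov, mode: str = "diploid",
                    seed: int = 0, search: str = "random") -> ClusterResult:
    """Run the rearrangement search on one breakpoint cluster and classify
    the converged structure."""
    chrom, bps = cluster.chrom, cluster.positions
    flank = int(round(lib.mu_IS + 3 * lib.sigma_IS))
    pairs = extract_region_pairs(alignments, chrom, bps[0] - flank - 1000,
                                 bps[-1] + flank + 1000)
    region = ra.prepare_region(chrom, bps, pairs, ev.starts, lib, cov)
    bounds = ra.estimate_cn_bounds(region)
    if search == "hill":
        result = ra.hill_climb_search(region, bounds, mode=mode)
    else:
        result = ra.run_search(region, bounds, mode=mode, seed=seed)
    calls = classify_structure(result.allele_a, result.allele_b, chrom, bps,
                               result.score.total)
    return ClusterResult(cluster, result, calls)


def call_variants(bam: str, reference: str, lib, cov, mask=None,
                  mode: str = "diploid", seed: int = 0, chroms=None,
                  max_bps: int = 8, search: str = "random",
                  max_block_len: int = MAX_BLOCK_LEN):
    """Full caller: breakpoint clusters per chromosome, randomized search on
    each, classified calls.  Deterministic given (seed, inputs)."""
    af = pysam.AlignmentFile(bam)
    if chroms is None:
        chroms = list(af.references)
    calls: list[SVCall] = []
    cluster_results: list[ClusterResult] = []
    for chrom in chroms:
        clusters, ev = bp.detect_breakpoint_clusters(af, chrom, lib, mask,
                                                     max_bps=max_bps)
        for idx, cluster in enumerate(clusters):
            if any(e - s > max_block_len for s, e in cluster.blocks):
                continue
            sub_seed = (seed * 100003 + idx * 257 + hash(chrom) % 9973) % (2 ** 31)
            try:
                cr = resolve_cluster(af, cluster, ev, lib, cov, mode=mode,
                                     seed=sub_seed, search=search)
            except (nm.ModelError, ValueError):
                continue
            cluster_results.append(cr)
            calls.extend(cr.calls)
    af.close()
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls, cluster_results
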