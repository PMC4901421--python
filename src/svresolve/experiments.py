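"""Benchmark experiments: planted-rearrangement studies run end to end.

Each function builds a synthetic study (reference, planted events, 30X
paired-end 101 bp reads with insert 500 +- 50), runs the caller and
measures the outcome.  Problem sizes follow the package's standard desk-
scale protocol: events are spaced >= 20 kb apart so their breakpoint
clusters are independent, and copy-neutral stretches between events serve
as the CN2 fitting regions.
"""

from __future__ import annotations

import math
import os
import tempfile

import numpy as np

from . import breakpoints as bp
from . import null_models as nm
from . import rearrange as ra
from . import synthetic_benchmark as sb
from . import longread_validation as lv
from .interpret import write_vcf
from .pipeline import call_variants, extract_region_pairs, fit_null_models

READ_LEN = 101
MU_IS = 500.0
SIGMA_IS = 50.0
DEPTH = 30


def _derive(seed: int, k: int) -> int:
    return (seed * 1000003 + k * 7919 + 13) % (2 ** 31)


def _neutral_gaps(events, contig_len, margin=3000, min_len=8000):
    """Copy-neutral windows between planted events."""
    regions = sorted(sb._event_region(e) for e in events)
    gaps = []
    prev = 0
    for s, e in regions + [(contig_len, contig_len)]:
        if s - margin - (prev + margin) >= min_len:
            gaps.append(("chr1", prev + margin, s - margin))
        prev = e
    return gaps


def _simulate_study(workdir, events, contig_len, seed, depth=DEPTH,
                    decorate_prob=0.3):
    ref = sb.random_reference(os.path.join(workdir, "ref.fa"),
                              {"chr1": contig_len}, seed=_derive(seed, 1))
    haps, truth = sb.plant_svs(ref, events, seed=_derive(seed, 2),
                               decorate_prob=decorate_prob)
    bam = sb.simulate_to_bam(haps, ref, depth,
                             os.path.join(workdir, "sim.bam"),
                             read_len=READ_LEN, mu_is=MU_IS,
                             sigma_is=SIGMA_IS, seed=_derive(seed, 3))
    neutral = _neutral_gaps(events, contig_len)
    lib, cov, mask = fit_null_models(bam, ref, neutral_regions=neutral)
    return ref, haps, truth, bam, lib, cov, mask


# ---------------------------------------------------------------------------
# Formula fidelity
# ---------------------------------------------------------------------------

def hand_fixture_region():
    """A five-pair region with written-out models, for checking the score
    formula against a by-hand evaluation."""
    lib = nm.LibraryModel("normal", mu_IS=500.0, sigma_IS=50.0)
    cov = nm.CoverageModel(window=100, mode="normal", mu_RD=30.0, sigma_RD=5.0,
                           mu_PC=74.0, sigma_PC=8.0)
    bps = [1000, 1500]
    pair_coords = [
        # (s1, e1, strand1, s2, e2, strand2)
        (500, 601, +1, 900, 1001, -1),
        (700, 801, +1, 1080, 1181, -1),
        (1000, 1101, +1, 1400, 1501, -1),
        (1100, 1201, +1, 1500, 1601, -1),
        (1250, 1351, -1, 1500, 1601, -1),   # one aberrant-orientation pair
    ]
    pairs = [ra.PairObs(*c) for c in pair_coords]
    starts = np.sort(np.array([c[0] for c in pair_coords]
                              + [c[3] for c in pair_coords]))
    region = ra.prepare_region("chr1", bps, pairs, starts, lib, cov)
    return region, pair_coords


def hand_score_reference(region, pair_coords) -> float:
    """Literal transcription of the composite score for the reference
    structure: identity projection, no novel junctions."""
    lib, cov = region.lib, region.cov
    n = len(pair_coords)
    sum_is = 0.0
    sum_po = 0.0
    for s1, e1, st1, s2, e2, st2 in pair_coords:
        insert = max(e1, e2) - min(s1, s2)
        ld = (-math.log(lib.sigma_IS * math.sqrt(2 * math.pi))
              - 0.5 * ((insert - lib.mu_IS) / lib.sigma_IS) ** 2)
        sum_is += max(ld, -50.0)
        left_fwd = st1 > 0 if s1 <= s2 else st2 > 0
        right_rev = (st2 < 0) if s1 <= s2 else (st1 < 0)
        sum_po += 1.0 if (left_fwd and right_rev) else 0.0
    sum_rd = 0.0
    w = cov.window
    start = region.region_start
    n_win = (region.region_end - start) // w
    all_starts = sorted([c[0] for c in pair_coords] + [c[3] for c in pair_coords])
    for i in range(n_win):
        lo, hi = start + i * w, start + (i + 1) * w
        obs = sum(1 for s in all_starts if lo <= s < hi)
        ld = (-math.log(cov.sigma_RD * math.sqrt(2 * math.pi))
              - 0.5 * ((obs - cov.mu_RD) / cov.sigma_RD) ** 2)
        sum_rd += max(ld, -50.0)
    tau = (-math.log(lib.sigma_IS * math.sqrt(2 * math.pi))) \
        / (-math.log(cov.sigma_RD * math.sqrt(2 * math.pi)))
    return sum_is * (1 + sum_po / n) + tau * sum_rd * (1 - 0.0)


def run_formula_fidelity() -> dict:
    region, coords = hand_fixture_region()
    impl = ra.score_structure(region, ra.reference_structure(1),
                              ra.reference_structure(1)).total
    hand = hand_score_reference(region, coords)
    r, p = nm.nb_from_moments(10.0, 20.0)
    from scipy.stats import nbinom
    mean = nbinom.mean(r, 1 - p)
    var = nbinom.var(r, 1 - p)
    rel = max(abs(mean - 10.0) / 10.0, abs(var - 20.0) / 20.0)
    return {"score_formula_abs_error": abs(impl - hand),
            "nb_moment_roundtrip_rel_error": rel}


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

def _oracle_events(rng, n_clusters, spacing, start=20000):
    """Heterozygous 2-3-block events on a 20 kb grid."""
    events = []
    for i in range(n_clusters):
        base = start + i * spacing
        kind = ["DEL_INV", "INV_DUP", "DEL_DUP", "DEL_INV_DUP"][i % 4]
        b1 = int(rng.integers(300, 600))
        b2 = int(rng.integers(300, 600))
        if kind == "DEL_INV":
            iv = {"a": (base, base + b1), "b": (base + b1, base + b1 + b2)}
        elif kind == "INV_DUP":
            iv = {"span": (base, base + b1), "insert_at": base + b1 + b2}
        elif kind == "DEL_DUP":
            iv = {"a": (base, base + b1), "b": (base + b1, base + b1 + b2)}
        else:
            b3 = int(rng.integers(300, 600))
            iv = {"a": (base, base + b1), "b": (base + b1, base + b1 + b2),
                  "c": (base + b1 + b2, base + b1 + b2 + b3)}
        events.append(sb.PlantedSV(kind, "chr1", iv, zygosity="het"))
    return events


def run_oracle_equivalence(seed: int, n_clusters: int = 50,
                           workdir: str | None = None) -> dict:
    """Randomized search vs exhaustive enumeration on small clusters.

    Heterozygous complex events are planted on one contig; for each, the
    truth breakpoints define the cluster and both searches run in the
    single-altered-allele module.  Agreement = the randomized search's best
    score reaches the enumerated global maximum.
    """
    rng = np.random.default_rng(_derive(seed, 10))
    spacing = 20000
    events = _oracle_events(rng, n_clusters, spacing)
    contig_len = 25000 + n_clusters * spacing
    with tempfile.TemporaryDirectory(dir=workdir) as wd:
        ref, haps, truth, bam, lib, cov, mask = _simulate_study(
            wd, events, contig_len, seed)
        import pysam
        af = pysam.AlignmentFile(bam)
        ev = bp.collect_evidence(af, "chr1", lib)
        hits = 0
        n_done = 0
        for i, rec in enumerate(truth):
            bps = sorted({rec.region[0], rec.region[1],
                          *[c for j in rec.junctions for c in (j[0], j[2])]})
            flank = int(round(lib.mu_IS + 3 * lib.sigma_IS))
            pairs = extract_region_pairs(af, "chr1", bps[0] - flank - 1000,
                                         bps[-1] + flank + 1000)
            region = ra.prepare_region("chr1", bps, pairs, ev.starts, lib, cov)
            bounds = ra.estimate_cn_bounds(region)
            try:
                oracle = ra.brute_force_search(region, bounds,
                                               mode="heterozygous")
            except nm.ModelError:
                continue
            res = ra.run_search(region, bounds, mode="heterozygous",
                                seed=_derive(seed, 100 + i))
            n_done += 1
            if res.score.total >= oracle.score.total - 1e-6 * abs(oracle.score.total):
                hits += 1
        af.close()
    return {"rate": hits / n_done if n_done else float("nan"), "n": n_done}


# ---------------------------------------------------------------------------
# Simple-SV recovery
# ---------------------------------------------------------------------------

def run_simple_recovery(seed: int, zygosity: str = "hom",
                        n_events: int = 20, workdir: str | None = None) -> dict:
    """Planted deletions (500 bp - 10 kb) at 30X, full pipeline, matched by
    strict >50 % reciprocal overlap."""
    sizes = [500, 1000, 2000, 5000, 10000]
    spacing = 25000
    events = []
    for i in range(n_events):
        base = 20000 + i * spacing
        size = sizes[i % len(sizes)]
        events.append(sb.PlantedSV("DEL", "chr1", {"span": (base, base + size)},
                                   zygosity=zygosity))
    contig_len = 30000 + n_events * spacing
    with tempfile.TemporaryDirectory(dir=workdir) as wd:
        ref, haps, truth, bam, lib, cov, mask = _simulate_study(
            wd, events, contig_len, seed)
        calls, _ = call_variants(bam, ref, lib, cov, mask, mode="diploid",
                                 seed=_derive(seed, 20))
    res = sb.evaluate_simple(calls, truth)["DEL"]
    matched_gt = 0
    for t in truth:
        ti = sb._truth_interval(t)
        for c in calls:
            if (c.type == "DEL"
                    and sb.reciprocal_overlap((c.start, c.end), ti) > 0.5):
                if c.genotype == t.zygosity:
                    matched_gt += 1
                break
    return {"sensitivity": res["sensitivity"], "fdr": res["fdr"],
            "n_truth": res["n_truth"], "n_called": res["n_called"],
            "genotype_accuracy": matched_gt / len(truth),
            "n_extra_calls": sum(1 for c in calls if c.type != "DEL")}


# ---------------------------------------------------------------------------
# Complex-SV recovery
# ---------------------------------------------------------------------------

def _layout_of_structure(structure, bps):
    return [(bps[b - 1], bps[b], "+" if o > 0 else "-") for b, o in structure]


def _layouts_equal(a, b, tol=50):
    if len(a) != len(b):
        return False
    for (s1, e1, o1), (s2, e2, o2) in zip(a, b):
        if o1 != o2 or abs(s1 - s2) > tol or abs(e1 - e2) > tol:
            return False
    return True


def run_csv_recovery(seed: int, n_each: int = 10,
                     workdir: str | None = None) -> dict:
    """Deletion-inversion and inverted-duplication events at 30X: junction-
    level recovery plus the rate of exactly reproduced block structures."""
    rng = np.random.default_rng(_derive(seed, 30))
    spacing = 20000
    events = []
    for i in range(2 * n_each):
        base = 20000 + i * spacing
        b1 = int(rng.integers(600, 1500))
        b2 = int(rng.integers(600, 1500))
        if i % 2 == 0:
            ev = sb.PlantedSV("DEL_INV", "chr1",
                              {"a": (base, base + b1),
                               "b": (base + b1, base + b1 + b2)},
                              zygosity="hom")
        else:
            ev = sb.PlantedSV("INV_DUP", "chr1",
                              {"span": (base, base + b1),
                               "insert_at": base + b1 + b2},
                              zygosity="hom")
        events.append(ev)
    contig_len = 30000 + 2 * n_each * spacing
    with tempfile.TemporaryDirectory(dir=workdir) as wd:
        ref, haps, truth, bam, lib, cov, mask = _simulate_study(
            wd, events, contig_len, seed)
        calls, cluster_results = call_variants(bam, ref, lib, cov, mask,
                                               mode="diploid",
                                               seed=_derive(seed, 31))
    pred_juncs = {}
    exact = 0
    for i, rec in enumerate(truth):
        overlapping = [cr for cr in cluster_results
                       if cr.cluster.positions[-1] > rec.region[0] - 2000
                       and cr.cluster.positions[0] < rec.region[1] + 2000]
        juncs = []
        got_exact = False
        for cr in overlapping:
            bps_c = cr.cluster.positions
            layouts = []
            for st in (cr.result.allele_a, cr.result.allele_b):
                lay = _layout_of_structure(st, bps_c)
                layouts.append(lay)
                for j in sb.layout_junctions(lay, bps_c[0], bps_c[-1]):
                    if j not in juncs:
                        juncs.append(j)
            if (_layouts_equal(layouts[0], rec.layout)
                    and _layouts_equal(layouts[1], rec.layout)):
                got_exact = True
        pred_juncs[i] = juncs
        exact += got_exact
    res = sb.evaluate_csv(pred_juncs, truth)
    res["exact_structure_rate"] = exact / len(truth)
    res["n_events"] = len(truth)
    return res


# ---------------------------------------------------------------------------
# Long-read validation
# ---------------------------------------------------------------------------

def run_longread_validation(seed: int, n_reads: int = 20,
                            workdir: str | None = None) -> dict:
    """Error-free 8 kb long reads from an altered haplotype: the true call
    must collect unanimous support, a fabricated call on unaltered sequence
    none, and a tandem-repeat region must be flagged non-assessable."""
    with tempfile.TemporaryDirectory(dir=workdir) as wd:
        ref = sb.random_reference(os.path.join(wd, "ref.fa"),
                                  {"chr1": 60000}, seed=_derive(seed, 40))
        sv_region = (30000, 32000)
        events = [sb.PlantedSV("DEL", "chr1", {"span": sv_region},
                               zygosity="hom")]
        haps, truth = sb.plant_svs(ref, events, seed=_derive(seed, 41),
                                   decorate_prob=0.0)
        reads = lv.simulate_long_reads(haps, ref, "chr1", sv_region, n_reads,
                                       read_len=8000, seed=_derive(seed, 42))
        true_res = lv.validate_sv(ref, "chr1", sv_region, [], reads, ploidy=2)
        fake_region = (10000, 11500)
        fake_reads = lv.simulate_long_reads(haps, ref, "chr1", fake_region,
                                            n_reads, read_len=8000,
                                            seed=_derive(seed, 43))
        fake_res = lv.validate_sv(ref, "chr1", fake_region, [], fake_reads,
                                  ploidy=2)
        repeat_assessable = lv.assess_region("AC" * 500)
        rng = np.random.default_rng(_derive(seed, 44))
        clean_assessable = lv.assess_region("".join(rng.choice(list("ACGT"), 1000)))
    return {"sval_true": true_res.s_val,
            "m_true": true_res.m,
            "all_support_true": float(all(s > 0 for s in true_res.read_scores)),
            "sval_fake": fake_res.s_val,
            "m_fake": fake_res.m,
            "repeat_flagged_nonassessable": float(not repeat_assessable),
            "random_region_assessable": float(clean_assessable)}


# ---------------------------------------------------------------------------
# Null control
# ---------------------------------------------------------------------------

def run_null_control(seed: int, contig_len: int = 5_000_000,
                     workdir: str | None = None) -> dict:
    """Reads simulated from an unaltered reference: the caller should stay
    silent, and whatever VCF it writes must parse as valid."""
    import pysam
    with tempfile.TemporaryDirectory(dir=workdir) as wd:
        ref = sb.random_reference(os.path.join(wd, "ref.fa"),
                                  {"chr1": contig_len}, seed=_derive(seed, 50))
        haps, _ = sb.plant_svs(ref, [], seed=0)
        bam = sb.simulate_to_bam(haps, ref, DEPTH,
                                 os.path.join(wd, "sim.bam"),
                                 seed=_derive(seed, 51))
        neutral = [("chr1", s, s + 50000)
                   for s in range(100000, 700000, 60000)]
        lib, cov, mask = fit_null_models(bam, ref, neutral_regions=neutral)
        calls, _ = call_variants(bam, ref, lib, cov, mask, mode="diploid",
                                 seed=_derive(seed, 52))
        vcf_path = os.path.join(wd, "calls.vcf")
        write_vcf(calls, ref, "null_sample", vcf_path)
        ok = True
        try:
            vf = pysam.VariantFile(vcf_path)
            _ = list(vf.fetch()) if vf.index else list(vf)
        except Exception:
            ok = False
    return {"n_calls": len(calls), "vcf_valid": float(ok)}
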