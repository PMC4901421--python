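import numpy as np
import pysam
import pytest

import svresolve as sv
from svresolve import breakpoints as bp
from svresolve import rearrange as ra
from svresolve.pipeline import extract_region_pairs


@pytest.fixture(scope="session")
def mini_study(tmp_path_factory):
    """A small diploid study shared across tests: 160 kb contig carrying a
    homozygous deletion, a heterozygous deletion and a homozygous
    inversion, sequenced at 30X."""
    wd = tmp_path_factory.mktemp("mini_study")
    ref = sv.random_reference(str(wd / "ref.fa"), {"chr1": 160000}, seed=101)
    events = [
        sv.PlantedSV("DEL", "chr1", {"span": (40000, 41500)}, zygosity="hom"),
        sv.PlantedSV("DEL", "chr1", {"span": (80000, 81000)}, zygosity="het"),
        sv.PlantedSV("INV", "chr1", {"span": (120000, 122000)}, zygosity="hom"),
    ]
    haps, truth = sv.plant_svs(ref, events, seed=102)
    bam = sv.simulate_to_bam(haps, ref, 30, str(wd / "sim.bam"), seed=103)
    neutral = [("chr1", 2000, 36000), ("chr1", 45000, 76000)]
    lib = sv.fit_library_model(bam, neutral)
    cov = sv.fit_coverage_model(bam, neutral)
    af = pysam.AlignmentFile(bam)
    evidence = bp.collect_evidence(af, "chr1", lib)
    af.close()
    return {"ref": ref, "bam": bam, "haps": haps, "truth": truth,
            "lib": lib, "cov": cov, "evidence": evidence, "events": events}


@pytest.fixture(scope="session")
def null_study(tmp_path_factory):
    """Reads simulated from an unaltered 200 kb reference at 30X."""
    wd = tmp_path_factory.mktemp("null_study")
    ref = sv.random_reference(str(wd / "ref.fa"), {"chr1": 200000}, seed=201)
    haps, _ = sv.plant_svs(ref, [], seed=0)
    bam = sv.simulate_to_bam(haps, ref, 30, str(wd / "sim.bam"), seed=202)
    lib = sv.fit_library_model(bam, [("chr1", 5000, 100000)])
    cov = sv.fit_coverage_model(bam, [("chr1", 5000, 100000)])
    return {"ref": ref, "bam": bam, "lib": lib, "cov": cov}


def region_for_cluster(study, bps):
    """Scoring context for a cluster of truth breakpoints."""
    lib, cov = study["lib"], study["cov"]
    flank = int(round(lib.mu_IS + 3 * lib.sigma_IS))
    af = pysam.AlignmentFile(study["bam"])
    pairs = extract_region_pairs(af, "chr1", bps[0] - flank - 1000,
                                 bps[-1] + flank + 1000)
    af.close()
    return ra.prepare_region("chr1", bps, pairs, study["evidence"].starts,
                             lib, cov)
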