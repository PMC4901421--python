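import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyfaidx import Fasta

import svresolve as sv
from svresolve import synthetic_benchmark as sb


@pytest.fixture(scope="module")
def ref(tmp_path_factory):
    wd = tmp_path_factory.mktemp("sbref")
    return sb.random_reference(str(wd / "ref.fa"), {"chr1": 100000}, seed=77)


class TestPlantSvs:
    def test_hom_deletion_length_bookkeeping(self, ref):
        events = [sb.PlantedSV("DEL", "chr1", {"span": (50000, 51000)},
                               zygosity="hom")]
        haps, truth = sb.plant_svs(ref, events, seed=1, decorate_prob=0.0)
        fa = Fasta(ref, as_raw=True)
        for hap in haps:
            seq = sb.haplotype_sequence(hap["chr1"], fa, "chr1")
            assert len(seq) == 100000 - 1000

    def test_het_inversion_alters_one_haplotype(self, ref):
        events = [sb.PlantedSV("INV", "chr1", {"span": (40000, 42000)},
                               zygosity="het")]
        haps, _ = sb.plant_svs(ref, events, seed=1, decorate_prob=0.0)
        fa = Fasta(ref, as_raw=True)
        whole = str(fa["chr1"][:])
        alt = sb.haplotype_sequence(haps[0]["chr1"], fa, "chr1")
        unaltered = sb.haplotype_sequence(haps[1]["chr1"], fa, "chr1")
        assert unaltered == whole
        assert alt == (whole[:40000] + sb.revcomp(whole[40000:42000])
                       + whole[42000:])

    def test_inverted_duplication_sequence(self, ref):
        events = [sb.PlantedSV("INV_DUP", "chr1",
                               {"span": (30000, 31000), "insert_at": 33000},
                               zygosity="hom")]
        haps, truth = sb.plant_svs(ref, events, seed=1, decorate_prob=0.0)
        fa = Fasta(ref, as_raw=True)
        whole = str(fa["chr1"][:])
        alt = sb.haplotype_sequence(haps[0]["chr1"], fa, "chr1")
        expected = (whole[:33000] + sb.revcomp(whole[30000:31000])
                    + whole[33000:])
        assert alt == expected

    def test_overlapping_events_rejected(self, ref):
        events = [sb.PlantedSV("DEL", "chr1", {"span": (1000, 3000)}),
                  sb.PlantedSV("INV", "chr1", {"span": (2000, 4000)})]
        with pytest.raises(ValueError, match="overlap"):
            sb.plant_svs(ref, events, seed=1)

    def test_decorations_add_sequence_at_junctions(self, ref):
        events = [sb.PlantedSV("DEL", "chr1", {"span": (50000, 51000)},
                               zygosity="hom")]
        haps, truth = sb.plant_svs(ref, events, seed=5, decorate_prob=1.0)
        fa = Fasta(ref, as_raw=True)
        seq = sb.haplotype_sequence(haps[0]["chr1"], fa, "chr1")
        deco_len = sum(len(s) for _, s in truth[0].decorations)
        assert len(seq) == 100000 - 1000 + deco_len

    @pytest.mark.parametrize("svtype,intervals,layout", [
        ("DEL", {"span": (10, 20)}, []),
        ("INV", {"span": (10, 20)}, [(10, 20, "-")]),
        ("DUP_TANDEM", {"span": (10, 20)}, [(10, 20, "+"), (10, 20, "+")]),
        ("TRA", {"span": (10, 20), "insert_at": 30},
         [(20, 30, "+"), (10, 20, "+")]),
        ("DEL_INV", {"a": (10, 20), "b": (20, 30)}, [(20, 30, "-")]),
        ("INV_DUP", {"span": (10, 20), "insert_at": 30},
         [(10, 20, "+"), (20, 30, "+"), (10, 20, "-")]),
    ])
    def test_event_layouts(self, svtype, intervals, layout):
        ev = sb.PlantedSV(svtype, "chr1", intervals)
        assert sb._event_layout(ev) == layout


class TestLayoutJunctions:
    def test_deletion_has_one_novel_junction(self):
        assert sb.layout_junctions([], 100, 200) == [(100, "+", 200, "+")]

    def test_inversion_has_two(self):
        j = sb.layout_junctions([(100, 200, "-")], 100, 200)
        assert j == [(100, "+", 200, "-"), (100, "-", 200, "+")]

    def test_reference_layout_has_none(self):
        assert sb.layout_junctions([(100, 200, "+")], 100, 200) == []


class TestSimulateReads:
    def test_pair_count_matches_expectation(self, ref):
        haps, _ = sb.plant_svs(ref, [], seed=0)
        pairs = sb.simulate_reads(haps, ref, depth=20, seed=3)
        expected = 2 * round(10 * 100000 / 202)
        assert len(pairs) == pytest.approx(expected, rel=0.02)

    def test_error_free_reads_are_substrings(self, ref):
        haps, _ = sb.plant_svs(ref, [], seed=0)
        fa = Fasta(ref, as_raw=True)
        seq = sb.haplotype_sequence(haps[0]["chr1"], fa, "chr1").upper()
        pairs = sb.simulate_reads(haps, ref, depth=0.5, error_rate=0.0, seed=4)
        for p in pairs[:50]:
            assert p.seq1 in seq
            assert sb.revcomp(p.seq2) in seq

    def test_same_seed_byte_identical_fastq(self, ref, tmp_path):
        haps, _ = sb.plant_svs(ref, [], seed=0)
        for tag in ("a", "b"):
            pairs = sb.simulate_reads(haps, ref, depth=1, seed=9,
                                      error_rate=0.01)
            sb.write_fastq(pairs, str(tmp_path / tag))
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_insert_length_moments_converge(self, ref):
        haps, _ = sb.plant_svs(ref, [], seed=0)
        rng_pairs = sb.simulate_reads(haps, ref, depth=25, seed=11)
        isz = np.array([p.isize for p in rng_pairs])
        assert isz.mean() == pytest.approx(500, rel=0.01)
        assert isz.std() == pytest.approx(50, rel=0.05)


class TestReciprocalOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 100), (0, 100), 1.0),
        ((0, 100), (50, 150), 0.5),
        ((0, 100), (200, 300), 0.0),
        ((0, 1000), (400, 500), 0.1),
    ])
    def test_examples(self, a, b, expected):
        assert sb.reciprocal_overlap(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 1000), st.integers(1, 500),
           st.integers(0, 1000), st.integers(1, 500))
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a, b = (s1, s1 + l1), (s2, s2 + l2)
        ro = sb.reciprocal_overlap(a, b)
        assert 0.0 <= ro <= 1.0
        assert ro == sb.reciprocal_overlap(b, a)


def truth_record(svtype, span, zygosity="hom"):
    return sb.TruthRecord(svtype, zygosity, "chr1", span, {"span": span})


class TestEvaluateSimple:
    def test_exact_calls_score_perfectly(self):
        truth = [truth_record("DEL", (100, 200)),
                 truth_record("INV", (500, 900))]
        calls = [("DEL", "chr1", 100, 200), ("INV", "chr1", 500, 900)]
        res = sb.evaluate_simple(calls, truth)
        for svtype in ("DEL", "INV"):
            assert res[svtype]["sensitivity"] == 1.0
            assert res[svtype]["fdr"] == 0.0

    def test_one_spurious_call_sets_fdr(self):
        truth = [truth_record("DEL", (100, 200))]
        calls = [("DEL", "chr1", 100, 200), ("DEL", "chr1", 5000, 6000)]
        res = sb.evaluate_simple(calls, truth)
        assert res["DEL"]["fdr"] == pytest.approx(1 / 2)

    def test_forty_percent_overlap_is_miss_and_fp(self):
        truth = [truth_record("DEL", (0, 100))]
        calls = [("DEL", "chr1", 60, 160)]  # 40 % reciprocal overlap
        res = sb.evaluate_simple(calls, truth)
        assert res["DEL"]["sensitivity"] == 0.0
        assert res["DEL"]["fp"] == 1

    def test_exactly_half_overlap_not_tp(self):
        truth = [truth_record("DEL", (0, 100))]
        res = sb.evaluate_simple([("DEL", "chr1", 50, 150)], truth)
        assert res["DEL"]["sensitivity"] == 0.0

    def test_dup_flavours_share_fp_pool(self):
        truth = [truth_record("DUP_TANDEM", (100, 200)),
                 truth_record("DUP_DISPERSED", (1000, 1100))]
        # a tandem call landing on the dispersed truth is not an FP
        calls = [("DUP_TANDEM", "chr1", 1000, 1100)]
        res = sb.evaluate_simple(calls, truth)
        assert res["DUP_TANDEM"]["sensitivity"] == 0.0
        assert res["DUP_TANDEM"]["fp"] == 0


class TestEvaluateCsv:
    def test_full_junction_recovery(self):
        rec = sb.TruthRecord("DEL_INV", "hom", "chr1", (100, 300),
                             {}, [(200, 300, "-")],
                             sb.layout_junctions([(200, 300, "-")], 100, 300))
        res = sb.evaluate_csv({0: list(rec.junctions)}, [rec])
        assert res["junction_sensitivity"] == 1.0
        assert res["total_fp"] == 0

    def test_partial_prediction_counts_missing_junctions(self):
        # deletion-only interpretation of a deletion-inversion event
        rec = sb.TruthRecord("DEL_INV", "hom", "chr1", (100, 300),
                             {}, [(200, 300, "-")],
                             sb.layout_junctions([(200, 300, "-")], 100, 300))
        pred = [(100, "+", 200, "+")]   # junction of a plain deletion of [100,200)
        res = sb.evaluate_csv({0: pred}, [rec])
        assert res["per_event"][0]["tp"] == 0
        assert res["per_event"][0]["fp"] == 1
        assert res["junction_sensitivity"] == 0.0

    def test_coordinate_tolerance(self):
        rec = sb.TruthRecord("DEL", "hom", "chr1", (100, 300), {}, [],
                             [(100, "+", 300, "+")])
        assert sb.evaluate_csv({0: [(130, "+", 330, "+")]},
                               [rec])["junction_sensitivity"] == 1.0
        assert sb.evaluate_csv({0: [(160, "+", 300, "+")]},
                               [rec])["junction_sensitivity"] == 0.0


class TestRankNormalize:
    def test_worked_example(self):
        assert list(sb.rank_normalize([3, 1, 2])) == [1.0, 0.0, 0.5]

    def test_single_score(self):
        assert list(sb.rank_normalize([4.2])) == [1.0]


class TestProjectionAlignment:
    def test_bam_round_trip_depth(self, ref, tmp_path):
        import pysam
        haps, _ = sb.plant_svs(ref, [], seed=0)
        bam = sb.simulate_to_bam(haps, ref, 10, str(tmp_path / "x.bam"), seed=2)
        af = pysam.AlignmentFile(bam)
        n = af.count("chr1", 40000, 60000)
        af.close()
        expected = 10 * 20000 / 101
        assert n == pytest.approx(expected, rel=0.05)

    def test_deletion_junction_produces_soft_clips(self, ref, tmp_path):
        import pysam
        events = [sb.PlantedSV("DEL", "chr1", {"span": (50000, 52000)},
                               zygosity="hom")]
        haps, _ = sb.plant_svs(ref, events, seed=1, decorate_prob=0.0)
        bam = sb.simulate_to_bam(haps, ref, 30, str(tmp_path / "d.bam"), seed=2)
        af = pysam.AlignmentFile(bam)
        clipped = [r for r in af.fetch("chr1", 49500, 50500)
                   if r.cigartuples and any(op == 4 for op, _ in r.cigartuples)]
        long_pairs = [r for r in af.fetch("chr1", 49000, 50000)
                      if abs(r.template_length) > 650]
        af.close()
        assert len(clipped) > 5
        assert len(long_pairs) > 20
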