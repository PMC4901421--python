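import random

import numpy as np
import pysam
import pytest

import svresolve as sv
from svresolve import breakpoints as bp
from svresolve import null_models as nm

LIB = nm.LibraryModel("normal", mu_IS=500, sigma_IS=50)


def make_pair(insert=510, left_strand=+1, right_strand=-1, clip=(0, 0),
              clip_qual=(0.0, 0.0), read_len=(101, 101)):
    return bp.ReadPairObservation("chr1", 1000, 1101, left_strand,
                                  1000 + insert - 101, 1000 + insert,
                                  right_strand, insert, clip, clip_qual,
                                  read_len)


class TestClassifyReadPair:
    def test_insert_beyond_three_sigma_is_size_aberrant(self):
        flags = bp.classify_read_pair(make_pair(insert=700), LIB)
        assert flags.size_aberrant and not flags.orientation_aberrant

    def test_concordant_pair_raises_no_flags(self):
        flags = bp.classify_read_pair(make_pair(insert=510), LIB)
        assert not flags.any

    def test_small_clip_fraction_not_clipped(self):
        # 8 of 101 bases clipped at high quality: below the 10 % fraction
        flags = bp.classify_read_pair(
            make_pair(clip=(8, 0), clip_qual=(35.0, 0.0)), LIB)
        assert not flags.clipped

    def test_large_high_quality_clip_is_clipped(self):
        flags = bp.classify_read_pair(
            make_pair(clip=(15, 0), clip_qual=(35.0, 0.0)), LIB)
        assert flags.clipped

    def test_low_quality_clip_ignored(self):
        flags = bp.classify_read_pair(
            make_pair(clip=(15, 0), clip_qual=(10.0, 0.0)), LIB)
        assert not flags.clipped

    def test_non_fr_orientation_aberrant(self):
        flags = bp.classify_read_pair(make_pair(right_strand=+1), LIB)
        assert flags.orientation_aberrant


def anchors(*specs):
    return [bp.Anchor(s, s + 101, strand, i)
            for i, (s, strand) in enumerate(specs)]


class TestClusterDiscordant:
    def test_nearby_same_orientation_anchors_cluster(self):
        cl = bp.cluster_discordant(anchors((1000, +1), (1100, +1)), LIB)
        assert len(cl) == 1 and len(cl[0].anchors) == 2

    def test_distant_anchors_split(self):
        cl = bp.cluster_discordant(anchors((1000, +1), (11000, +1)), LIB)
        assert len(cl) == 2

    def test_orientation_partitions_clusters(self):
        cl = bp.cluster_discordant(anchors((1000, +1), (1000, -1)), LIB)
        assert len(cl) == 2
        assert {c.strand for c in cl} == {+1, -1}

    def test_input_order_invariance(self):
        specs = [(int(p), s) for p, s in
                 zip(np.random.default_rng(3).integers(0, 50000, 60),
                     [+1, -1] * 30)]
        a = bp.cluster_discordant(anchors(*specs), LIB)
        random.Random(0).shuffle(specs)
        b = bp.cluster_discordant(anchors(*specs), LIB)
        key = lambda cl: sorted((x.start, x.strand) for x in cl.anchors)
        assert sorted(map(key, a)) == sorted(map(key, b))


def evidence_with_depth(depth=30, read_len=100, span=20000):
    """Synthetic ChromEvidence with uniform depth."""
    ev = bp.ChromEvidence("chr1", read_len)
    step = read_len / depth
    ev.starts = np.arange(0, span, step).astype(np.int64)
    return ev


class TestAssignBreakpoint:
    def test_split_reads_above_20_percent_of_rd(self):
        ev = evidence_with_depth(30)
        cluster = bp.DiscordantCluster(+1, anchors((900, +1), (950, +1))[:2])
        clips = [bp.ClipEvidence(1000, "R")] * 7
        out = bp.assign_breakpoint(cluster, clips, ev, LIB)
        assert len(out) == 1 and out[0].position == 1000
        assert out[0].split_support == 7

    def test_insufficient_aberrant_fraction_yields_none(self):
        ev = evidence_with_depth(30)
        cl = bp.DiscordantCluster(+1, anchors(*[(900 + i, +1) for i in range(8)]))
        out = bp.assign_breakpoint(cl, [], ev, LIB)  # 8 <= 0.30 * 30
        assert out == []

    def test_forward_cluster_fallback_is_rightmost_end(self):
        ev = evidence_with_depth(30)
        cl = bp.DiscordantCluster(
            +1, [bp.Anchor(s, e, +1, i) for i, (s, e) in
                 enumerate([(899, 1000), (909, 1010), (919, 1020)] * 4)])
        out = bp.assign_breakpoint(cl, [], ev, LIB)  # 12 > 0.30 * 30
        assert len(out) == 1 and out[0].position == 1020

    def test_reverse_cluster_fallback_is_leftmost_start(self):
        ev = evidence_with_depth(30)
        cl = bp.DiscordantCluster(
            -1, [bp.Anchor(s, s + 101, -1, i) for i, s in
                 enumerate([2000, 2010, 2020] * 4)])
        out = bp.assign_breakpoint(cl, [], ev, LIB)
        assert out[0].position == 2000


def cands(*positions, pair_ids=()):
    out = []
    for i, pos in enumerate(positions):
        pids = set(pair_ids[i]) if pair_ids else set()
        out.append(bp.BreakpointCandidate("chr1", pos, +1, 5, 5, 30.0, pids))
    return out


class TestLinkBreakpoints:
    def test_mate_links_are_transitive(self):
        c = cands(1000, 50000, 100000, pair_ids=[{1}, {1, 2}, {2}])
        clusters = bp.link_breakpoints(c)
        assert len(clusters) == 1
        assert clusters[0].positions == [1000, 50000, 100000]

    def test_proximity_under_1kb_groups_pairs(self):
        c = cands(1000, 10000, 10500, 20000,
                  pair_ids=[{1}, {1}, {2}, {2}])
        clusters = bp.link_breakpoints(c)
        assert len(clusters) == 1 and len(clusters[0].positions) == 4

    def test_distant_pairs_stay_separate(self):
        c = cands(1000, 10000, 15000, 24000,
                  pair_ids=[{1}, {1}, {2}, {2}])
        clusters = bp.link_breakpoints(c)
        assert len(clusters) == 2

    def test_isolated_breakpoints_dropped(self):
        clusters = bp.link_breakpoints(cands(1000, pair_ids=[{1}]))
        assert clusters == []


class TestSubgroupCluster:
    def test_small_cluster_unchanged(self):
        cl = bp.BreakpointCluster("chr1", [100, 200, 300])
        assert bp.subgroup_cluster(cl, 8) == [cl]

    def test_cut_at_widest_gap(self):
        pos = [0, 100, 200, 300, 400, 10000, 10100, 10200, 10300, 10400]
        subs = bp.subgroup_cluster(bp.BreakpointCluster("chr1", pos), 8)
        assert [len(s.positions) for s in subs] == [5, 5]
        assert subs[0].positions[-1] == 400 and subs[1].positions[0] == 10000

    def test_even_spacing_splits_in_half(self):
        pos = list(range(0, 1600, 100))
        subs = bp.subgroup_cluster(bp.BreakpointCluster("chr1", pos), 8)
        assert [len(s.positions) for s in subs] == [8, 8]
        assert [p for s in subs for p in s.positions] == pos


class TestDetection:
    def test_planted_hom_deletion_cluster_recovered(self, mini_study):
        af = pysam.AlignmentFile(mini_study["bam"])
        clusters, _ = bp.detect_breakpoint_clusters(af, "chr1",
                                                    mini_study["lib"])
        af.close()
        hits = [c for c in clusters
                if any(abs(p - 40000) <= 10 for p in c.positions)
                and any(abs(p - 41500) <= 10 for p in c.positions)]
        assert hits, [c.positions for c in clusters]

    def test_no_clusters_on_unaltered_reference(self, null_study):
        af = pysam.AlignmentFile(null_study["bam"])
        clusters, _ = bp.detect_breakpoint_clusters(af, "chr1",
                                                    null_study["lib"])
        af.close()
        # false-positive tolerance: <= 1 cluster per megabase on 200 kb
        assert len(clusters) <= 1

    def test_cluster_debug_dump(self, tmp_path):
        clusters = [bp.BreakpointCluster("chr1", [100, 900])]
        c = bp.BreakpointCandidate("chr1", 100, +1, 7, 12, 30.0)
        bed = tmp_path / "c.bed"
        tab = tmp_path / "c.tsv"
        bp.dump_clusters(clusters, str(bed), str(tab), [c])
        assert bed.read_text() == "chr1\t100\t900\t100,900\n"
        assert "chr1\t100\t+\t7\t12\t30.00" in tab.read_text()

    def test_masked_positions_are_excluded(self, mini_study):
        mask = sv.GenomeMask({"chr1": [(39000, 42000)]})
        af = pysam.AlignmentFile(mini_study["bam"])
        clusters, _ = bp.detect_breakpoint_clusters(af, "chr1",
                                                    mini_study["lib"], mask)
        af.close()
        for c in clusters:
            for p in c.positions:
                assert not mask.contains("chr1", p)
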