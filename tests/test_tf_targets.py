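"""Promoter-window target calling and HOT-region handling."""

import numpy as np
import pandas as pd
import pytest

from regnet import (PromoterWindow, call_all_targets, call_tf_targets,
                    detect_hot_regions, read_annotation)
from regnet.io_formats import PeakSet
from regnet.tf_targets import WINDOW_PRESETS, auto_hot_threshold


def _peakset(tf, centers, chrom="chrI", halfwidth=100, condition="L1"):
    rows = [(chrom, c - halfwidth, c + halfwidth, c, 1.0) for c in centers]
    return PeakSet(tf_id=tf, condition=condition,
                   peaks=pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                     "center", "score"]))


def _annotation(tss=10_000, strand="+", length=3000):
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length + 1, tss + 1
    gff = (f"chrI\ts\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID=gA\n"
           f"chrI\ts\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\tID=gA.t1;Parent=gA\n")
    return read_annotation(gff)


class TestPromoterWindow:
    def test_plus_strand_bounds(self):
        assert PromoterWindow(1000, 500).around(10_000, "+") == (9000, 10_500)

    def test_minus_strand_mirrors(self):
        assert PromoterWindow(1000, 500).around(10_000, "-") == (9501, 11_001)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            PromoterWindow(0, 0)


class TestCallTargets:
    def test_800bp_upstream_is_a_target(self):
        edges = call_tf_targets(_peakset("tfA", [9200]), _annotation())
        assert edges == [("tfA", "gA", "gene")]

    def test_600bp_downstream_is_not(self):
        edges = call_tf_targets(_peakset("tfA", [10_600]), _annotation())
        assert edges == []

    def test_window_boundaries_half_open(self):
        win = WINDOW_PRESETS["default"]
        assert call_tf_targets(_peakset("t", [9000]), _annotation(), win)   # included
        assert not call_tf_targets(_peakset("t", [10_500]), _annotation(), win)

    def test_minus_strand_gene(self):
        ann = _annotation(strand="-")
        # 800 bp upstream of a minus-strand TSS is at tss + 800
        assert call_tf_targets(_peakset("t", [10_800]), ann)
        assert not call_tf_targets(_peakset("t", [10_600 - 1200]), ann)

    def test_mirna_anchored_at_five_prime(self):
        gff = "chrI\ts\tpre_miRNA\t5001\t5080\t.\t-\t.\tID=mir-9\n"
        ann = read_annotation(gff)
        # 5' end of the minus-strand pre-miRNA is 0-based 5079
        edges = call_tf_targets(_peakset("t", [5079 + 800]), ann)
        assert edges == [("t", "mir-9", "mirna")]

    def test_strand_symmetry_under_reflection(self, rng):
        """Mirroring all coordinates and strands leaves the edge set invariant."""
        C = 40_000
        for _ in range(5):
            tss = int(rng.integers(5000, 30_000))
            centers = [int(rng.integers(tss - 2000, tss + 2000)) for _ in range(6)]
            fwd = call_tf_targets(_peakset("t", centers), _annotation(tss, "+"))
            ref_centers = [C - 1 - c for c in centers]
            rev = call_tf_targets(_peakset("t", ref_centers),
                                  _annotation(C - 1 - tss, "-"))
            assert [e[1] for e in fwd] == [e[1] for e in rev]

    def test_multi_condition_union(self):
        ps1 = _peakset("tfA", [9200], condition="L1")
        ps2 = _peakset("tfA", [10_600], condition="L3")  # misses
        edges = call_all_targets([ps1, ps2], _annotation())
        assert edges == [("tfA", "gA", "gene")]

    def test_window_enlargement_is_monotone(self, small_bundle):
        ann = small_bundle.annotation
        ps = small_bundle.peaksets[0]
        strict = set(call_tf_targets(ps, ann, WINDOW_PRESETS["strict"]))
        default = set(call_tf_targets(ps, ann, WINDOW_PRESETS["default"]))
        relaxed = set(call_tf_targets(ps, ann, WINDOW_PRESETS["relaxed"]))
        assert strict <= default <= relaxed


class TestHotRegions:
    def test_sixteen_stacked_tfs_make_one_region(self):
        sets = [_peakset(f"tf{i}", [1200]) for i in range(16)]
        hot = detect_hot_regions(sets, window_bp=400, threshold=15)
        assert len(hot) == 1
        r = hot.regions.iloc[0]
        assert r.start <= 1000 and r.end >= 1400
        assert r.occupancy == 16

    def test_fourteen_tfs_below_threshold(self):
        sets = [_peakset(f"tf{i}", [1200]) for i in range(14)]
        assert len(detect_hot_regions(sets, threshold=15)) == 0

    def test_conditions_of_one_tf_count_once(self):
        sets = [_peakset("tfX", [1200], condition=c) for c in ("L1", "L2", "L3")]
        sets += [_peakset(f"tf{i}", [1200]) for i in range(13)]
        assert len(detect_hot_regions(sets, threshold=15)) == 0  # 14 distinct TFs

    def test_two_stacks_two_intervals_vs_bruteforce(self):
        sets = [_peakset(f"tf{i}", [1200, 11_200]) for i in range(16)]
        hot = detect_hot_regions(sets, window_bp=400, threshold=15)
        assert len(hot) == 2
        # brute-force position-wise occupancy scan
        for pos in range(0, 13_000):
            n = sum(1 for s in sets if any(
                p.start < pos + 200 and p.end > pos - 200
                for _, p in s.peaks.iterrows()))
            inside = ((hot.regions.start <= pos) & (pos < hot.regions.end)).any()
            assert inside == (n >= 15), f"position {pos}"

    def test_exclusion_removes_edges_even_in_promoter(self):
        ann = _annotation()
        sets = [_peakset(f"tf{i}", [9200]) for i in range(16)]
        hot = detect_hot_regions(sets, threshold=15)
        kept = call_tf_targets(sets[0], ann, hot=hot, hot_mode="keep")
        excl = call_tf_targets(sets[0], ann, hot=hot, hot_mode="exclude_overlap")
        assert kept and not excl

    def test_exclude_center_spares_off_hot_centers(self):
        ann = _annotation()
        sets = [_peakset(f"tf{i}", [9200]) for i in range(16)]
        hot = detect_hot_regions(sets, threshold=15)
        # peak overlapping the HOT region but centered outside it
        hot_end = int(hot.regions.iloc[0].end)
        ps = _peakset("tfZ", [hot_end + 50], halfwidth=200)
        assert not call_tf_targets(ps, ann, hot=hot, hot_mode="exclude_overlap")

    def test_exclusion_mode_requires_hot(self):
        with pytest.raises(ValueError):
            call_tf_targets(_peakset("t", [9200]), _annotation(),
                            hot=None, hot_mode="exclude_overlap")

    def test_threshold_autoscaling(self):
        assert auto_hot_threshold(22) == 15
        assert auto_hot_threshold(20) == 14


class TestTruthRecovery:
    def test_true_edges_recovered_with_no_background(self):
        from regnet import SimulationParams, simulate

        params = SimulationParams(seed=5, n_genes=200, n_tfs_annotated=20,
                                  n_tfs_assayed=8, n_mirnas=20, hot_region_count=0,
                                  hot_tf_count=8, background_peaks_per_tf=0.0,
                                  n_chromosomes=2, chrom_bp=1_200_000,
                                  mean_gene_targets_per_tf=30.0)
        bundle = simulate(params)
        called = set(call_all_targets(bundle.peaksets, bundle.annotation))
        truth = set(bundle.true_tf_edges)
        assert truth <= called
        # jitter is window-truncated, so recall is exact; the only false
        # positives are promoter-window coincidences where a pre-miRNA anchor
        # sits within ~1.5 kb of a target gene's TSS (gene windows themselves
        # cannot collide by the >=2.5 kb spacing rule)
        precision = len(truth) / len(called)
        assert precision >= 0.95
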