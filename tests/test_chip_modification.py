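"""Peak-to-TSS assignment, replicate summaries, ANOVA, metagene profiles."""

import numpy as np
import pytest
import scipy.stats

from itgscan import (
    ChipConfig,
    CoverageTrack,
    GeneRecord,
    GenomicInterval,
    PeakRecord,
    call_modified_genes,
    metagene_profile,
    one_way_anova,
    proportion_summary,
    summary_from_replicate_percentages,
    tss_window,
)
from oracles import brute_modified


def gene(gid, start, end, strand="+", chrom="chr1", cls="genic"):
    return GeneRecord(gid, GenomicInterval(chrom, start, end, strand), cls)


def peak(start, end, mark="H3K27ac", rep=1, chrom="chr1"):
    return PeakRecord(mark, rep, GenomicInterval(chrom, start, end))


class TestCallModifiedGenes:
    def test_peak_in_window_is_called(self):
        g = gene("g", 2000, 6000)  # TSS at 2000, window [0, 4001)
        calls = call_modified_genes([g], [peak(500, 900)])
        assert calls[0].modified

    def test_peak_ending_at_window_start_not_called(self):
        g = gene("g", 5000, 9000)  # window [3000, 7001)
        assert not call_modified_genes([g], [peak(2600, 3000)])[0].modified
        assert call_modified_genes([g], [peak(2600, 3001)])[0].modified

    def test_literal_plus_2kb_position_inside(self):
        g = gene("g", 5000, 9000)  # "+" TSS 5000; +2 kb position is 7000
        assert call_modified_genes([g], [peak(7000, 7300)])[0].modified
        assert not call_modified_genes([g], [peak(7001, 7300)])[0].modified

    def test_window_clipped_at_chromosome_start(self):
        g = gene("g", 500, 3000)
        chrom, lo, hi = tss_window(g)
        assert (lo, hi) == (0, 2501)

    def test_every_triple_present(self):
        genes = [gene("a", 5000, 9000), gene("b", 50000, 54000)]
        peaks = [peak(4000, 4500, "H3K4me3", 1), peak(4000, 4500, "H3K4me3", 2),
                 peak(100, 200, "H3K27ac", 1)]
        calls = call_modified_genes(genes, peaks)
        keys = {(c.gene_id, c.mark, c.replicate) for c in calls}
        assert len(keys) == len(calls) == 2 * 3  # 2 genes x 3 (mark, rep) pairs

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            genes = [gene(f"g{i}", s := int(rng.integers(0, 30000)),
                          s + int(rng.integers(1000, 5000)),
                          strand=str(rng.choice(["+", "-"])),
                          chrom=f"chr{rng.integers(1, 3)}")
                     for i in range(5)]
            peaks = [peak(s := int(rng.integers(0, 30000)),
                          s + int(rng.integers(100, 800)),
                          mark=str(rng.choice(["m1", "m2"])),
                          rep=int(rng.integers(1, 3)),
                          chrom=f"chr{rng.integers(1, 3)}")
                     for _ in range(12)]
            calls = call_modified_genes(genes, peaks)
            by_gene = {}
            for c in calls:
                by_gene.setdefault(c.gene_id, {})[(c.mark, c.replicate)] = c.modified
            for g in genes:
                assert by_gene[g.gene_id] == brute_modified(g, peaks, 2000)

    def test_invariant_under_peak_order(self):
        genes = [gene("g", 5000, 9000)]
        peaks = [peak(3000, 3400, rep=1), peak(6500, 6900, rep=2),
                 peak(100, 300, rep=3)]
        c1 = call_modified_genes(genes, peaks)
        c2 = call_modified_genes(genes, peaks[::-1])
        assert c1 == c2


class TestProportionSummary:
    def test_mixed_scale_convention(self):
        s = summary_from_replicate_percentages("H3K27ac", "genic",
                                               [64.1, 62.7, 62.1])
        assert round(s.mean_pct, 1) == 63.0
        assert round(s.stdev_fraction, 3) == 0.010

    def test_identical_replicates_zero_stdev(self):
        s = summary_from_replicate_percentages("m", "genic", [50.0, 50.0, 50.0])
        assert s.stdev_fraction == 0.0

    def test_matches_recomputation_from_raw_calls(self):
        rng = np.random.default_rng(12)
        genes = [gene(f"g{i}", 100000 * i + 5000, 100000 * i + 9000,
                      cls="genic" if i < 30 else "itg") for i in range(50)]
        peaks = []
        for g in genes:
            for rep in (1, 2):
                if rng.random() < 0.6:
                    t = g.interval.start
                    peaks.append(peak(t - 1000, t - 600, "m", rep,
                                      chrom=g.interval.chrom))
        classes = {g.gene_id: g.source_class for g in genes}
        calls = call_modified_genes(genes, peaks)
        for s in proportion_summary(calls, classes):
            n_class = sum(1 for c in classes.values() if c == s.gene_class)
            raw = [
                100 * sum(c.modified and classes[c.gene_id] == s.gene_class
                          and c.replicate == rep for c in calls) / n_class
                for rep in (1, 2)
            ]
            assert s.per_replicate_pct == pytest.approx(tuple(raw))
            assert s.mean_pct == pytest.approx(np.mean(raw))
            assert s.stdev_fraction == pytest.approx(
                np.std(np.array(raw) / 100, ddof=1))

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            proportion_summary([], {})


class TestOneWayAnova:
    def test_identical_groups_f_zero_p_one(self):
        assert one_way_anova([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_planted_separation_significant(self):
        f, p = one_way_anova([0.756, 0.759, 0.729], [0.445, 0.428, 0.448])
        assert p < 0.001

    def test_textbook_sums_of_squares(self):
        # groups {3,5,7} and {6,10,14}: grand mean 7.5
        # SS_between = 3*(5-7.5)^2 + 3*(10-7.5)^2 = 37.5 (df 1)
        # SS_within = (4+0+4) + (16+0+16) = 40 (df 4) -> F = 37.5/10 = 3.75
        f, p = one_way_anova([3, 5, 7], [6, 10, 14])
        assert f == pytest.approx(3.75)
        assert p == pytest.approx(float(scipy.stats.f.sf(3.75, 1, 4)))

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            a = rng.normal(0.6, 0.05, size=int(rng.integers(2, 8)))
            b = rng.normal(0.5, 0.05, size=int(rng.integers(2, 8)))
            f, p = one_way_anova(a, b)
            ref = scipy.stats.f_oneway(a, b)
            assert f == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_degenerate_zero_variance_unequal_means(self):
        f, p = one_way_anova([1, 1], [2, 2])
        assert p == 0.0 and np.isinf(f)


class TestMetageneProfile:
    def test_flat_coverage_gives_flat_unit_profile(self):
        track = CoverageTrack({"chr1": [(0, 1_000_000, 1.0)]})
        genes = [gene("g", 100000, 104000)]
        prof = metagene_profile(track, genes)
        assert len(prof.y) == 2 * 20 + 100
        np.testing.assert_allclose(prof.y, 1.0)

    def test_tss_concentrated_signal_peaks_at_tss_boundary(self):
        track = CoverageTrack({"chr1": [(99800, 100200, 5.0)]})
        genes = [gene("g", 100000, 104000)]
        prof = metagene_profile(track, genes)
        # TSS boundary sits between flank bin 19 and body bin 0 (index 20);
        # the signal straddles it so both adjacent bins carry the maximum
        assert prof.y.max() > 0
        assert prof.y[19] == prof.y.max() and prof.y[20] == prof.y.max()

    def test_minus_strand_profile_mirrors_plus(self):
        # signal 1 kb downstream of each TSS, mirrored layouts
        plus = [gene("p", 100000, 104000, strand="+")]
        minus = [gene("m", 100000, 104000, strand="-")]
        # trailing zero step equalizes the tracks' extent, hence genome mean
        t_plus = CoverageTrack({"chr1": [(100900, 101100, 3.0),
                                         (200000, 200010, 0.0)]})
        t_minus = CoverageTrack({"chr1": [(102900, 103100, 3.0),
                                          (200000, 200010, 0.0)]})
        y_p = metagene_profile(t_plus, plus).y
        y_m = metagene_profile(t_minus, minus).y
        np.testing.assert_allclose(y_p, y_m, rtol=1e-9)

    def test_short_gene_skipped(self):
        track = CoverageTrack({"chr1": [(0, 10000, 1.0)]})
        genes = [gene("tiny", 5000, 5050), gene("ok", 100000, 104000)]
        prof = metagene_profile(track, genes)
        assert prof.n_genes == 1

    def test_all_genes_short_rejected(self):
        track = CoverageTrack({"chr1": [(0, 10000, 1.0)]})
        with pytest.raises(ValueError):
            metagene_profile(track, [gene("tiny", 5000, 5050)])
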