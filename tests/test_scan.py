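"""Euclidean-distance statistic, windowing, null threshold and regions."""

import numpy as np
import pandas as pd
import pytest

from seedling_qtl.scan import (BulkSegregantScan, QTLRegion,
                               allele_frequencies, call_regions,
                               euclidean_distance, genotype_class_percentages,
                               intersect_gwas, null_threshold,
                               windowed_statistic)
from seedling_qtl.simulate import CrossDesign, SequencingModel

from conftest import make_marker_table


def brute_force_windows(profile: pd.DataFrame, window: int) -> pd.DataFrame:
    """Independent double-loop reimplementation of the windowed statistic."""
    rows = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        ed = sub["ed"].to_numpy()
        pos = sub["pos"].to_numpy()
        n = len(ed)
        if n < window:
            total = 0.0
            for v in ed:
                total += v
            rows.append((chrom, 0, pos[(n - 1) // 2], total ** 4, True))
            continue
        for start in range(n - window + 1):
            total = 0.0
            for j in range(start, start + window):
                total += ed[j]
            rows.append((chrom, start, pos[start + (window - 1) // 2],
                         total ** 4, False))
    return pd.DataFrame(rows, columns=["chrom", "window_start_idx", "mid_pos",
                                       "w_stat", "partial"])


def _freq_frame(fa_h, fa_l, chrom="chr1"):
    fa_h = np.atleast_1d(np.asarray(fa_h, dtype=float))
    fa_l = np.atleast_1d(np.asarray(fa_l, dtype=float))
    return pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, fa_h.size + 1) * 1000,
        "fa_H": fa_h, "fa_L": fa_l,
        "fA_H": 1 - fa_h, "fA_L": 1 - fa_l,
    })


class TestAlleleFrequencies:
    @pytest.mark.parametrize("alt,ref,expected", [
        (50, 50, 0.5), (100, 0, 1.0), (3, 9, 0.25)])
    def test_frequency_from_read_counts(self, alt, ref, expected):
        t = make_marker_table(1)
        t.loc[0, ["alt_bulk_high", "ref_bulk_high"]] = [alt, ref]
        f = allele_frequencies(t)
        assert f.loc[0, "fa_H"] == pytest.approx(expected)
        assert f.loc[0, "fA_H"] == pytest.approx(1 - expected)

    def test_zero_depth_markers_dropped_and_counted(self):
        t = make_marker_table(5)
        t.loc[2, ["alt_bulk_low", "ref_bulk_low"]] = 0
        f = allele_frequencies(t)
        assert len(f) == 4
        assert f.attrs["n_zero_depth_dropped"] == 1


class TestEuclideanDistance:
    def test_identical_bulks_zero(self):
        ed = euclidean_distance(_freq_frame(0.3, 0.3))["ed"]
        assert ed.iloc[0] == 0.0

    def test_maximal_divergence_sqrt2(self):
        ed = euclidean_distance(_freq_frame(1.0, 0.0))["ed"]
        assert ed.iloc[0] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_arithmetic_example(self):
        ed = euclidean_distance(_freq_frame(0.9, 0.1))["ed"]
        assert ed.iloc[0] == pytest.approx(np.sqrt(0.64 + 0.64), abs=1e-12)

    def test_symmetric_under_bulk_swap(self):
        rng = np.random.default_rng(0)
        fh, fl = rng.random(50), rng.random(50)
        a = euclidean_distance(_freq_frame(fh, fl))["ed"]
        b = euclidean_distance(_freq_frame(fl, fh))["ed"]
        np.testing.assert_allclose(a, b)

    def test_invariant_under_allele_relabeling(self):
        rng = np.random.default_rng(1)
        fh, fl = rng.random(50), rng.random(50)
        a = euclidean_distance(_freq_frame(fh, fl))["ed"]
        b = euclidean_distance(_freq_frame(1 - fh, 1 - fl))["ed"]
        np.testing.assert_allclose(a, b)


class TestWindowedStatistic:
    def test_uniform_window_value(self):
        prof = _freq_frame(np.full(100, 0.5), np.full(100, 0.5))
        prof["ed"] = 0.1
        w = windowed_statistic(prof, window=100)
        assert len(w) == 1
        assert w.loc[0, "w_stat"] == pytest.approx(10_000.0, rel=1e-12)

    def test_zero_profile_zero_everywhere(self):
        prof = _freq_frame(np.full(150, 0.5), np.full(150, 0.5))
        prof["ed"] = 0.0
        w = windowed_statistic(prof, window=100)
        assert (w["w_stat"] == 0).all()

    def test_two_window_example(self):
        prof = _freq_frame(np.full(101, 0.5), np.full(101, 0.5))
        prof["ed"] = 0.0
        prof.loc[100, "ed"] = 1.0
        w = windowed_statistic(prof, window=100)
        assert w["w_stat"].tolist() == [0.0, 1.0]

    def test_short_chromosome_single_flagged_window(self):
        prof = _freq_frame(np.full(30, 0.5), np.full(30, 0.5))
        prof["ed"] = 0.2
        w = windowed_statistic(prof, window=100)
        assert len(w) == 1 and w.loc[0, "partial"]
        assert w.loc[0, "w_stat"] == pytest.approx((30 * 0.2) ** 4)

    def test_empty_profile(self):
        prof = _freq_frame(np.array([]), np.array([]))
        prof["ed"] = np.nan
        assert windowed_statistic(prof.iloc[:0]).empty

    def test_matches_brute_force_multichrom(self):
        rng = np.random.default_rng(2)
        frames = []
        for chrom, n in (("chr1", 180), ("chr2", 37), ("chr3", 120)):
            f = _freq_frame(rng.random(n), rng.random(n), chrom=chrom)
            frames.append(f)
        prof = euclidean_distance(pd.concat(frames, ignore_index=True))
        for window in (5, 40, 100):
            fast = windowed_statistic(prof, window=window)
            slow = brute_force_windows(prof, window=window)
            pd.testing.assert_frame_equal(fast, slow, rtol=1e-12)

    def test_disjoint_tiling_mode(self):
        prof = _freq_frame(np.full(10, 0.5), np.full(10, 0.5))
        prof["ed"] = np.arange(10) / 10.0
        w = windowed_statistic(prof, window=5, sliding=False)
        assert len(w) == 2
        assert w["window_start_idx"].tolist() == [0, 5]


class TestNullThreshold:
    DESIGN = CrossDesign(n_f2=737, bulk_size=75)

    def test_vanishing_noise_limit(self):
        """Huge bulks at huge depth leave almost no sampling noise, so the
        null threshold collapses toward zero (orders of magnitude below the
        study-scale threshold)."""
        design = CrossDesign(n_f2=100000, tail_fraction=0.5, bulk_size=50000)
        seqm = SequencingModel(mean_depth_high=1e6, mean_depth_low=1e6,
                               error_rate=0.0, depth_dispersion=0.0)
        thr = null_threshold(design, seqm, n_markers=200, window=100,
                             n_sim=200, seed=0)
        thr_study = null_threshold(
            self.DESIGN, SequencingModel(mean_depth_high=1028,
                                         mean_depth_low=814),
            n_markers=200, window=100, n_sim=200, seed=0)
        assert thr < 0.01
        assert thr < 1e-4 * thr_study

    def test_threshold_decreases_with_bulk_size(self):
        seqm = SequencingModel(mean_depth_high=800, mean_depth_low=800)
        thr_small = null_threshold(self.DESIGN, seqm, n_markers=500,
                                   n_sim=300, seed=1)
        big = CrossDesign(n_f2=5000, bulk_size=500)
        thr_big = null_threshold(big, seqm, n_markers=500, n_sim=300, seed=1)
        assert thr_big < thr_small

    def test_too_few_simulations_rejected(self):
        with pytest.raises(ValueError):
            null_threshold(self.DESIGN, SequencingModel(), n_sim=50)

    def test_linked_null_exceeds_unlinked(self):
        """Bulk-drift autocorrelation along a linked chromosome inflates the
        windowed statistic, so the linked null threshold is far higher."""
        seqm = SequencingModel(mean_depth_high=800, mean_depth_low=800)
        pos_cm = np.linspace(0, 150, 500)
        thr_unlinked = null_threshold(self.DESIGN, seqm, n_markers=500,
                                      n_sim=200, seed=5, mode="familywise")
        thr_linked = null_threshold(self.DESIGN, seqm, n_markers=500,
                                    n_sim=200, seed=5, mode="familywise",
                                    pos_cm=pos_cm)
        assert thr_linked > 5 * thr_unlinked


class TestRegions:
    def _windows(self, positions, stats, chrom="chr1"):
        return pd.DataFrame({
            "chrom": chrom, "window_start_idx": np.arange(len(positions)),
            "mid_pos": positions, "w_stat": stats, "partial": False})

    def test_no_significant_markers(self):
        w = self._windows([10_000_000], [1.0])
        assert call_regions(w, threshold=2.0) == []

    def test_overlapping_flanks_merge(self):
        w = self._windows([10_000_000, 20_000_000], [5.0, 3.0])
        regions = call_regions(w, threshold=1.0, flank=8_000_000)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (2_000_000, 28_000_000)
        assert r.peak_pos == 10_000_000 and r.n_significant_markers == 2

    def test_distant_markers_split(self):
        w = self._windows([10_000_000, 30_000_000], [5.0, 3.0])
        regions = call_regions(w, threshold=1.0, flank=8_000_000)
        assert len(regions) == 2

    def test_clipping_to_chromosome(self):
        w = self._windows([1_000_000], [5.0])
        r = call_regions(w, 1.0, flank=8_000_000,
                         chrom_lengths={"chr1": 5_000_000})[0]
        assert (r.start, r.end) == (1, 5_000_000)

    def test_peak_tie_leftmost(self):
        w = self._windows([10_000_000, 12_000_000], [5.0, 5.0])
        r = call_regions(w, 1.0, flank=8_000_000)[0]
        assert r.peak_pos == 10_000_000


class TestGwasIntersection:
    REGIONS = [QTLRegion("chr1", 2_000_000, 28_000_000, 10_000_000, 5.0, 2)]

    def test_hit_inside_region_matched(self):
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [15_000_000]})
        out = intersect_gwas(self.REGIONS, hits)
        assert out.loc[0, "region_index"] == 0

    def test_boundary_is_closed(self):
        hits = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "pos": [2_000_000, 28_000_001]})
        out = intersect_gwas(self.REGIONS, hits)
        assert out.loc[0, "region_index"] == 0
        assert pd.isna(out.loc[1, "region_index"])

    def test_no_regions_all_unmatched(self):
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
        out = intersect_gwas([], hits)
        assert out["region_index"].isna().all()

    def test_unknown_chromosome_rejected(self):
        hits = pd.DataFrame({"chrom": ["chrX"], "pos": [1]})
        with pytest.raises(ValueError, match="chrX"):
            intersect_gwas(self.REGIONS, hits, chromosomes={"chr1"})


class TestGenotypeClassPercentages:
    def test_rounding_to_one_decimal(self):
        out = genotype_class_percentages({"C/C": 26, "G/G": 74}, 122)
        assert out == {"C/C": 21.3, "G/G": 60.7}


class TestScanModel:
    def test_end_to_end_localizes_strong_qtl(self):
        """A strong QTL on chr1 produces a region containing the causal
        position; summary reports it."""
        from seedling_qtl import simulate as sim

        gmap = sim.GeneticMapSpec(chromosomes=sim.default_genome(2),
                                  markers_per_chrom=300)
        qtl_pos = int(gmap.positions().query(
            "chrom == 'chr1'")["pos_bp"].iloc[150])
        design = sim.CrossDesign(n_f2=737, bulk_size=75, residual_sd=1.0,
                                 qtl_loci=(("chr1", qtl_pos, 1.5, 0.0),))
        seqm = sim.SequencingModel(mean_depth_high=1028, mean_depth_low=814)
        genos = sim.simulate_f2_population(gmap, design, 20)
        ph = sim.simulate_phenotypes(genos, design, 21)
        bulks = sim.select_bulks(ph, design)
        markers = sim.simulate_pooled_reads(genos, bulks, seqm, 22)
        res = BulkSegregantScan(markers, design=design, seqmodel=seqm,
                                n_sim=200).fit(seed=23)
        assert res.regions, "expected at least one QTL region"
        hit = [r for r in res.regions
               if r.chrom == "chr1" and r.start <= qtl_pos <= r.end]
        assert hit
        assert "QTL regions" in res.summary()
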