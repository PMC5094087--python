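"""Scan statistics: window tiling, Hp, Weir–Cockerham FST, Z-transform."""

import numpy as np
import pytest

from poolscan.vcfio import table_from_cohort
from poolscan.windows import (
    fst_from_freqs,
    fst_snp,
    make_windows,
    pooled_heterozygosity,
    compute_window_stats,
    window_fst,
    z_transform,
)

from conftest import small_config
from oracles import hp_brute_force, wc_theta_two_pop


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (500_000, [(0, 200_000), (100_000, 300_000), (200_000, 400_000),
                       (300_000, 500_000)]),
            (200_000, [(0, 200_000)]),
            (250_000, [(0, 200_000), (100_000, 250_000)]),  # truncated tail
            (80_000, [(0, 80_000)]),  # shorter than one window
        ],
    )
    def test_tiling(self, length, expected):
        wins = make_windows({"chr1": length})
        assert [(w.start, w.end) for w in wins] == expected

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 1000}, size=0)
        with pytest.raises(ValueError):
            make_windows({"chr1": 1000}, size=100, step=200)


class TestPooledHeterozygosity:
    def test_known_values(self):
        # one SNP with 10 maj / 10 min reads: maximal heterozygosity
        assert pooled_heterozygosity([10], [10], min_snps=1) == pytest.approx(0.5)
        # monomorphic window
        assert pooled_heterozygosity([10, 12], [0, 0], min_snps=1) == 0.0
        # (12,3) and (9,6): 2*21*9/30^2 = 0.42
        assert pooled_heterozygosity([12, 9], [3, 6], min_snps=1) == pytest.approx(0.42)

    def test_matches_brute_force_oracle_exactly(self):
        """Windowed Hp equals an explicit summation loop on random windows."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(1, 40)
            maj = rng.integers(0, 30, n)
            mn = np.minimum(rng.integers(0, 30, n), maj)
            if (maj + mn).sum() == 0:
                continue
            got = pooled_heterozygosity(maj, mn, min_snps=1)
            assert got == hp_brute_force(maj, mn)
            assert 0.0 <= got <= 0.5

    def test_min_snps_gives_missing_not_zero(self):
        assert np.isnan(pooled_heterozygosity([10] * 5, [5] * 5, min_snps=10))
        # zero-depth SNPs are not informative
        assert np.isnan(pooled_heterozygosity([0, 10], [0, 5], min_snps=2))

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            pooled_heterozygosity([-1], [0], min_snps=1)


class TestFstSnp:
    def test_fixed_difference_gives_one(self):
        assert fst_snp((0, 30), (30, 0)) == pytest.approx(1.0)

    def test_identical_pools_nonpositive(self):
        assert fst_snp((15, 15), (15, 15)) <= 0.0

    def test_frozen_value_from_oracle(self):
        """(15 alt / 30 reads) vs (5 alt / 30 reads), n=30,30 -> theta = 17/87."""
        got = fst_snp((15, 15), (25, 5))
        assert got == pytest.approx(17 / 87, abs=1e-15)
        assert got == pytest.approx(wc_theta_two_pop([0.5, 5 / 30], [30, 30]), abs=1e-15)

    def test_matches_transcribed_estimator_on_random_sites(self):
        rng = np.random.default_rng(77)
        p1 = rng.random(1000)
        p2 = rng.random(1000)
        got = fst_from_freqs(p1, p2, 30, 30)
        for i in range(1000):
            want = wc_theta_two_pop([p1[i], p2[i]], [30, 30])
            if np.isnan(want):
                assert np.isnan(got[i])
            else:
                assert got[i] == pytest.approx(want, abs=1e-12)
                assert got[i] <= 1.0

    def test_zero_depth_excluded(self):
        assert np.isnan(fst_snp((0, 0), (10, 5)))

    def test_hudson_estimator_available(self):
        assert fst_snp((0, 30), (30, 0), estimator="hudson") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fst_snp((10, 5), (10, 5), estimator="nope")

    def test_unequal_sample_sizes(self):
        got = fst_snp((10, 10), (35, 5), n_chrom1=20, n_chrom2=40)
        want = wc_theta_two_pop([0.5, 0.125], [20, 40])
        assert got == pytest.approx(want, abs=1e-12)


class TestWindowFst:
    def test_mean_of_per_snp_values(self):
        assert window_fst([1.0, 1.0], min_snps=2) == pytest.approx(1.0)
        assert window_fst([0.2, 0.4, 0.6], min_snps=3) == pytest.approx(0.4)

    def test_all_excluded_is_missing(self):
        assert np.isnan(window_fst([np.nan, np.nan], min_snps=1))
        assert np.isnan(window_fst([0.5], min_snps=10))


class TestZTransform:
    def test_symmetric_case(self):
        np.testing.assert_allclose(z_transform([0.0, 1.0, 2.0]), [-1.0, 0.0, 1.0])

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            z_transform([3.0, 3.0, 3.0])

    def test_standardization_identity(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5, 3, 500)
        z = z_transform(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        np.testing.assert_allclose(z_transform(3.5 * x + 2.0), z_transform(x), atol=1e-12)

    def test_groups_standardized_separately_and_nan_passthrough(self):
        x = np.array([0.0, 1.0, 2.0, np.nan, 10.0, 20.0, 30.0])
        g = np.array(["a", "a", "a", "a", "x", "x", "x"])
        z = z_transform(x, g)
        np.testing.assert_allclose(z[:3], [-1, 0, 1])
        assert np.isnan(z[3])
        np.testing.assert_allclose(z[4:], [-1, 0, 1])


class TestComputeWindowStats:
    def test_window_fst_equals_recomputed_per_snp_mean(self, small_cohort):
        """Per-window FST is exactly the mean of independently recomputed
        per-SNP Weir–Cockerham values over the window's eligible sites."""
        config, cohort = small_cohort
        table = table_from_cohort(cohort)
        stats = compute_window_stats(table, config.chrom_lengths)
        idx = table.chrom_slice("chr1")
        pos = table.pos[idx]
        ref = table.ref_reads[idx]
        alt = table.alt_reads[idx]
        rows = stats[stats.chrom == "chr1"].head(20)
        for row in rows.itertuples(index=False):
            sel = (pos >= row.start) & (pos < row.end)
            vals = []
            for i in np.flatnonzero(sel):
                v = fst_snp(
                    (int(ref[i, 0]), int(alt[i, 0])), (int(ref[i, 1]), int(alt[i, 1]))
                )
                if not np.isnan(v):
                    vals.append(v)
            want = np.mean(vals) if len(vals) >= 10 else np.nan
            got = row.fst_breed1_breed2
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_sweep_windows_have_depressed_hp(self, small_cohort):
        """Windows fully inside the intensity-1 sweep sit in the extreme low
        tail of the swept breed's Hp distribution."""
        config, cohort = small_cohort
        table = table_from_cohort(cohort)
        stats = compute_window_stats(table, config.chrom_lengths)
        sweep = config.sweeps[0]
        inside = (
            (stats.chrom == sweep.chrom)
            & (stats.start >= sweep.start)
            & (stats.end <= sweep.end)
        )
        neutral = ~(
            (stats.chrom == sweep.chrom)
            & (stats.start < sweep.end)
            & (stats.end > sweep.start)
        )
        hp = stats["hp_breed1"]
        assert inside.sum() >= 1
        assert hp[inside].max() < np.nanquantile(hp[neutral], 0.01)

    def test_autosomal_z_scores_standardized(self, small_cohort):
        config, cohort = small_cohort
        table = table_from_cohort(cohort)
        stats = compute_window_stats(table, config.chrom_lengths)
        auto = stats.chrom != "chrX"
        z = stats.loc[auto, "z_hp_breed2"].dropna()
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12
        zx = stats.loc[~auto, "z_hp_breed2"].dropna()
        assert abs(zx.mean()) < 1e-12
        assert abs(zx.std(ddof=1) - 1) < 1e-12
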