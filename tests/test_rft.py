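"""T->Z matching, smoothness estimation, cluster inference, conjunctions, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from tfspm.glm import build_design_matrix, fit_cellwise_glm, make_contrast, contrast_tmap
from tfspm.rft import (
    SmoothnessEstimate,
    cluster_inference,
    conjunction,
    estimate_smoothness,
    nonstationary_extent,
    permutation_oracle,
    simulate_smooth_field,
    t_to_z,
)

GRID = (101, 57)  # 0-500 ms x 4-60 Hz at 5 ms / 1 Hz
TIMES = np.arange(0.0, 501.0, 5.0)
FREQS = np.arange(4.0, 61.0, 1.0)
FWHM_GRID = (96.0 / 5.0, 12.0 / 1.0)


def uniform_smoothness(fwhm_t_ms=96.0, fwhm_f_hz=12.0) -> SmoothnessEstimate:
    rpv = np.full(GRID, 1.0 / (fwhm_t_ms / 5.0 * fwhm_f_hz / 1.0))
    return SmoothnessEstimate(
        fwhm_t_ms=fwhm_t_ms, fwhm_f_hz=fwhm_f_hz, rpv=rpv,
        resel_count=float(rpv.sum()), grid_step_ms=5.0, grid_step_hz=1.0,
    )


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        for df in (3, 30, 300):
            assert t_to_z(np.array([0.0]), df)[0] == pytest.approx(0.0, abs=1e-12)

    def test_large_df_limit(self):
        T = np.linspace(-4, 4, 33)
        Z = t_to_z(T, 1e6)
        assert np.abs(Z - T).max() < 1e-3

    def test_monotone_and_antisymmetric(self):
        T = np.linspace(-8, 8, 101)
        Z = t_to_z(T, 12)
        assert (np.diff(Z) > 0).all()
        np.testing.assert_allclose(Z, -t_to_z(-T, 12), atol=1e-12)

    def test_extreme_values_stay_finite(self):
        Z = t_to_z(np.array([-50.0, 50.0]), 500)
        assert np.isfinite(Z).all() and Z[1] > 8

    def test_bad_df(self):
        with pytest.raises(ValueError):
            t_to_z(np.zeros(3), 0)


class TestSmoothness:
    def test_known_fwhm_recovered(self):
        """96 ms x 12 Hz smoothed noise is recovered within 15% per axis."""
        rng = np.random.default_rng(0)
        maps = np.stack([simulate_smooth_field(GRID, FWHM_GRID, rng) for _ in range(500)])
        est = estimate_smoothness(maps, 5.0, 1.0)
        assert abs(est.fwhm_t_ms - 96.0) / 96.0 < 0.15
        assert abs(est.fwhm_f_hz - 12.0) / 12.0 < 0.15

    def test_unsmoothed_noise_fwhm_small(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((500,) + GRID)
        est = estimate_smoothness(maps, 5.0, 1.0)
        assert est.fwhm_t_ms / 5.0 < 2.0 and est.fwhm_f_hz / 1.0 < 2.0

    def test_uniform_smoothness_rpv_cv(self):
        rng = np.random.default_rng(2)
        maps = np.stack([simulate_smooth_field(GRID, FWHM_GRID, rng) for _ in range(500)])
        est = estimate_smoothness(maps, 5.0, 1.0)
        cv = est.rpv.std() / est.rpv.mean()
        assert cv < 0.2

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            estimate_smoothness(np.zeros((10,) + GRID), 5.0, 1.0)


class TestClusterInference:
    def test_threshold_above_max_gives_empty_table(self):
        Z = np.full(GRID, 1.0)
        ct = cluster_inference(Z, TIMES, FREQS, uniform_smoothness(), height_p=0.01)
        assert len(ct) == 0 and len(ct.significant) == 0

    def test_corrected_not_below_uncorrected(self):
        rng = np.random.default_rng(3)
        Z = simulate_smooth_field(GRID, FWHM_GRID, rng) + 1.0
        ct = cluster_inference(Z, TIMES, FREQS, uniform_smoothness())
        assert len(ct) > 0
        assert (ct.table.p_ext_corr >= ct.table.p_ext_unc - 1e-12).all()
        assert (ct.table.p_peak_corr >= ct.table.p_peak_unc - 1e-12).all()

    def test_extent_p_monotone_in_cluster_size(self):
        """A bigger blob never gets a larger corrected extent p."""
        sm = uniform_smoothness()
        ps = []
        for radius in (3.0, 6.0, 12.0):
            Z = np.zeros(GRID)
            ti, fi = np.meshgrid(np.arange(GRID[0]), np.arange(GRID[1]), indexing="ij")
            blob = ((ti - 50) / radius) ** 2 + ((fi - 28) / radius) ** 2 < 1.0
            Z[blob] = 3.0
            ct = cluster_inference(Z, TIMES, FREQS, sm)
            assert len(ct) == 1
            ps.append(ct.table.p_ext_corr[0])
        assert ps[0] >= ps[1] >= ps[2]

    def test_peak_tie_break(self):
        Z = np.zeros(GRID)
        Z[10:13, 10:13] = 3.0  # flat-topped cluster: tie on the peak
        ct = cluster_inference(Z, TIMES, FREQS, uniform_smoothness())
        assert ct.table.peak_time_ms[0] == TIMES[10]
        assert ct.table.peak_freq_hz[0] == FREQS[10]

    def test_bad_height(self):
        with pytest.raises(ValueError):
            cluster_inference(np.zeros(GRID), TIMES, FREQS, uniform_smoothness(),
                              height_p=0.8)


class TestNonstationaryExtent:
    def test_uniform_rpv_matches_stationary_formula(self):
        rpv = np.full(GRID, 0.0043)
        cells = np.zeros(GRID, dtype=bool)
        cells[20:30, 10:20] = True
        k = cells.sum()
        assert nonstationary_extent(cells, rpv) == pytest.approx(k * 0.0043, rel=1e-10)

    def test_linear_in_rpv(self):
        rng = np.random.default_rng(4)
        rpv = rng.uniform(0.001, 0.01, GRID)
        cells = rng.random(GRID) < 0.2
        assert nonstationary_extent(cells, 2 * rpv) == pytest.approx(
            2 * nonstationary_extent(cells, rpv), rel=1e-12
        )

    def test_rough_region_yields_larger_resel_extent(self):
        """Equal-cell clusters weigh more where the field is rougher."""
        rng = np.random.default_rng(5)
        smooth_half = np.stack(
            [simulate_smooth_field((101, 28), FWHM_GRID, rng) for _ in range(300)]
        )
        rough_half = rng.standard_normal((300, 101, 29))
        maps = np.concatenate([smooth_half, rough_half], axis=2)
        est = estimate_smoothness(maps, 5.0, 1.0)
        cells_smooth = np.zeros((101, 57), dtype=bool)
        cells_smooth[40:60, 5:15] = True
        cells_rough = np.zeros((101, 57), dtype=bool)
        cells_rough[40:60, 40:50] = True
        assert (
            nonstationary_extent(cells_rough, est.rpv)
            > 2 * nonstationary_extent(cells_smooth, est.rpv)
        )


class TestConjunction:
    def test_single_map_is_identity(self):
        rng = np.random.default_rng(6)
        Z = simulate_smooth_field(GRID, FWHM_GRID, rng)
        zmin, _ = conjunction(Z, TIMES, FREQS, uniform_smoothness())
        np.testing.assert_array_equal(zmin, Z)

    def test_minimum_bounds_every_input(self):
        rng = np.random.default_rng(7)
        maps = np.stack([simulate_smooth_field(GRID, FWHM_GRID, rng) for _ in range(4)])
        zmin, _ = conjunction(maps, TIMES, FREQS, uniform_smoothness())
        assert (zmin <= maps).all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conjunction(np.zeros((2, 10, 10)), TIMES, FREQS, uniform_smoothness())

    def test_common_effect_recovered_across_seeds(self):
        """A locus present in every subject survives the min-statistic test."""
        bump = np.zeros(GRID)
        ti, fi = np.meshgrid(np.arange(GRID[0]), np.arange(GRID[1]), indexing="ij")
        bump = 4.0 * np.exp(-(((ti - 40) / 10.0) ** 2 + ((fi - 40) / 6.0) ** 2) / 2.0)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            maps = np.stack(
                [simulate_smooth_field(GRID, FWHM_GRID, rng) + bump for _ in range(6)]
            )
            _, ct = conjunction(maps, TIMES, FREQS, uniform_smoothness())
            sig = ct.significant
            covered = any(
                (abs(row.peak_time_ms - TIMES[40]) <= 50)
                and (abs(row.peak_freq_hz - FREQS[40]) <= 8)
                for _, row in sig.iterrows()
            )
            hits += covered
        assert hits >= 16


class TestPermutationOracle:
    @staticmethod
    def setup_design(n_per=12, n_cells=(20, 10), effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(2):
            for st in ("eyes", "mosaic"):
                for i in range(n_per):
                    rows.append(dict(subject=s, stimulus_type=st))
        lab = pd.DataFrame(rows)
        y = rng.standard_normal((len(lab),) + n_cells)
        if effect:
            sel = (lab.stimulus_type == "eyes").to_numpy()
            y[np.ix_(sel, range(8, 12), range(4, 7))] += effect
        dm = build_design_matrix(lab)
        return lab, y, dm

    def test_exchangeable_data_is_unremarkable(self):
        lab, y, dm = self.setup_design(seed=8)
        y = np.tile(y[:1], (len(y), 1, 1))  # identical trials: labels carry nothing
        sm = uniform_smoothness()
        sm = SmoothnessEstimate(96.0, 12.0, np.full((20, 10), 0.004), 0.8, 5.0, 1.0)
        rep = permutation_oracle(y, dm, make_contrast(dm, "stimulus_type"), sm,
                                 n_perm=120, seed=1)
        assert rep["p_peak"] > 0.5 and rep["p_extent"] > 0.5

    def test_resolution_bound_and_warning(self):
        lab, y, dm = self.setup_design(seed=9)
        sm = SmoothnessEstimate(96.0, 12.0, np.full((20, 10), 0.004), 0.8, 5.0, 1.0)
        rep = permutation_oracle(y, dm, make_contrast(dm, "stimulus_type"), sm,
                                 n_perm=50, seed=2)
        assert rep["p_peak"] >= 1.0 / 51 and rep["p_extent"] >= 1.0 / 51
        assert "warning" in rep

    def test_strong_effect_detected(self):
        lab, y, dm = self.setup_design(effect=3.0, seed=10)
        sm = SmoothnessEstimate(96.0, 12.0, np.full((20, 10), 0.004), 0.8, 5.0, 1.0)
        rep = permutation_oracle(y, dm, make_contrast(dm, "stimulus_type"), sm,
                                 n_perm=199, seed=3)
        assert rep["p_peak"] <= 0.01
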