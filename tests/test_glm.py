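"""Design coding, least-squares identities, ReML variance recovery, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfspm.glm import (
    ContrastSpec,
    DesignError,
    adjust_maps,
    build_design_matrix,
    contrast_tmap,
    effect_size_window,
    estimate_nonsphericity,
    fit_cellwise_glm,
    make_contrast,
)


def full_labels(n_subjects=6, per_cell=3, rng=None):
    """Balanced trial table: stimulus type x direction x laterality x subject."""
    rows = []
    trial = 0
    for s in range(n_subjects):
        for st in ("eyes", "mosaic"):
            for d in ("averted", "straight"):
                for ch in ("amy_L", "amy_R"):
                    for _ in range(per_cell):
                        rows.append(dict(subject=s, stimulus_type=st, direction=d,
                                         channel=ch, trial_index=trial))
                        trial += 1
    lab = pd.DataFrame(rows)
    if rng is not None:
        lab = lab.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    return lab


def two_condition_labels(n_per=30):
    rows = [dict(subject=0, stimulus_type=st, trial_index=i)
            for i, st in enumerate(["eyes"] * n_per + ["mosaic"] * n_per)]
    return pd.DataFrame(rows)


class TestDesignMatrix:
    def test_full_design_coding(self):
        dm = build_design_matrix(full_labels())
        assert dm.n_columns == 13  # 8 cells + 5 subject blocks
        assert np.linalg.matrix_rank(dm.X) == 13
        assert (dm.X[:, :8].sum(axis=1) == 1).all()  # one cell per row

    def test_balanced_orthogonality(self):
        dm = build_design_matrix(full_labels())
        cells, blocks = dm.X[:, :8], dm.X[:, 8:]
        assert np.abs(cells.T @ blocks).max() < 1e-10

    def test_duplicate_covariate_rejected(self):
        lab = full_labels(n_subjects=2)
        cov = np.random.default_rng(0).standard_normal(len(lab))
        with pytest.raises(DesignError, match="rank"):
            build_design_matrix(lab, covariates=np.column_stack([cov, cov]))

    def test_empty_cell_names_culprit(self):
        lab = full_labels(n_subjects=2)
        lab = lab[~((lab.subject == 1) & (lab.stimulus_type == "mosaic")
                    & (lab.direction == "straight") & (lab.channel == "amy_R"))]
        with pytest.raises(DesignError, match="subject 1"):
            build_design_matrix(lab)

    def test_contrast_spec_validation(self):
        with pytest.raises(DesignError):
            ContrastSpec(weights=np.zeros(13))


class TestFit:
    def test_contrast_equals_two_sample_t(self):
        """The eyes-mosaics contrast reproduces the pooled-variance t exactly."""
        rng = np.random.default_rng(1)
        lab = two_condition_labels(30)
        y = rng.standard_normal((60, 4))
        y[:30] += 0.8
        dm = build_design_matrix(lab)
        fit = fit_cellwise_glm(y, dm)
        T, df = contrast_tmap(fit, make_contrast(dm, "stimulus_type"))
        for j in range(4):
            t_ref = stats.ttest_ind(y[:30, j], y[30:, j]).statistic
            assert abs(T[j] - t_ref) < 1e-8
        assert df == 58

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        lab = full_labels(n_subjects=3, per_cell=4)
        y = rng.standard_normal((len(lab), 5))
        dm = build_design_matrix(lab)
        fit = fit_cellwise_glm(y, dm)
        resid = y - dm.X @ fit.beta
        ip = np.abs(dm.X.T @ resid)
        bound = 1e-8 * np.linalg.norm(dm.X, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert (ip < bound).all()

    def test_default_df(self):
        lab = full_labels()
        y = np.random.default_rng(3).standard_normal((len(lab), 2))
        fit = fit_cellwise_glm(y, build_design_matrix(lab))
        assert fit.df == len(lab) - 13

    def test_null_t_follows_student_distribution(self):
        """Empirical null T at one cell matches t(df) (KS test)."""
        rng = np.random.default_rng(4)
        lab = two_condition_labels(12)
        dm = build_design_matrix(lab)
        c = make_contrast(dm, "stimulus_type")
        y = rng.standard_normal((24, 500))  # 500 independent null fits
        fit = fit_cellwise_glm(y, dm)
        T, df = contrast_tmap(fit, c)
        assert stats.kstest(T, "t", args=(df,)).pvalue > 0.01

    def test_contrast_sign_symmetry_and_guards(self):
        lab = two_condition_labels(10)
        dm = build_design_matrix(lab)
        y = np.random.default_rng(5).standard_normal((20, 3))
        fit = fit_cellwise_glm(y, dm)
        c = make_contrast(dm, "stimulus_type")
        T1, _ = contrast_tmap(fit, c)
        T2, _ = contrast_tmap(fit, ContrastSpec(weights=-c.weights))
        np.testing.assert_allclose(T2, -T1, atol=1e-12)
        with pytest.raises(DesignError):
            contrast_tmap(fit, ContrastSpec(weights=np.ones(5)))

    def test_block_coding_invariance(self):
        """Main-effect T is identical under a different subject-block basis."""
        from dataclasses import replace

        rng = np.random.default_rng(6)
        lab = full_labels(n_subjects=4, per_cell=2)
        y = rng.standard_normal((len(lab), 3))
        dm = build_design_matrix(lab)
        c = make_contrast(dm, "stimulus_type")
        T1, _ = contrast_tmap(fit_cellwise_glm(y, dm), c)
        # dummy (one-hot, drop-last) coding spans the same nuisance space
        dummies = np.column_stack(
            [(lab.subject == s).to_numpy(float) for s in range(3)]
        )
        dm2 = replace(dm, X=np.column_stack([dm.X[:, :8], dummies]))
        T2, _ = contrast_tmap(fit_cellwise_glm(y, dm2), c)
        np.testing.assert_allclose(T1, T2, atol=1e-8)


class TestNonSphericity:
    def make_data(self, ratio, n_per=250, n_cells=50, seed=7):
        rng = np.random.default_rng(seed)
        lab = two_condition_labels(n_per)
        sd = np.where(lab.stimulus_type == "eyes", np.sqrt(ratio), 1.0)
        y = rng.standard_normal((2 * n_per, n_cells)) * sd[:, None]
        return lab, y

    def test_equal_variances_recovered(self):
        lab, y = self.make_data(1.0)
        ns = estimate_nonsphericity(y, build_design_matrix(lab))
        ratio = ns.variances[0] / ns.variances[1]
        assert 0.8 <= ratio <= 1.25

    def test_fourfold_variance_recovered(self):
        lab, y = self.make_data(4.0)
        ns = estimate_nonsphericity(y, build_design_matrix(lab))
        ratio = ns.variances[0] / ns.variances[1]
        assert abs(ratio - 4.0) <= 1.0

    def test_whitened_refit_matches_ols_when_homoscedastic(self):
        lab, y = self.make_data(1.0, seed=8)
        dm = build_design_matrix(lab)
        c = make_contrast(dm, "stimulus_type")
        T_ols, _ = contrast_tmap(fit_cellwise_glm(y, dm), c)
        ns = estimate_nonsphericity(y, dm)
        T_w, _ = contrast_tmap(
            fit_cellwise_glm(y, dm, weights=ns.weights, df=ns.df_satterthwaite), c
        )
        assert np.max(np.abs(T_w - T_ols) / np.abs(T_ols)) < 0.02

    def test_small_groups_rejected(self):
        lab, y = self.make_data(1.0, n_per=4)
        with pytest.raises(DesignError):
            estimate_nonsphericity(y, build_design_matrix(lab))


class TestAdjustedMaps:
    def test_subject_offsets_removed(self):
        lab = full_labels(n_subjects=3, per_cell=2)
        offsets = lab.subject.to_numpy(float) * 10.0
        y = np.tile(offsets[:, None], (1, 6))
        adj = adjust_maps(y, lab)
        for m in adj.values():
            assert np.abs(m).max() < 1e-8 * 10.0

    def test_constant_shift_invariant(self):
        rng = np.random.default_rng(9)
        lab = full_labels(n_subjects=2, per_cell=2)
        y = rng.standard_normal((len(lab), 4))
        a = adjust_maps(y, lab)
        b = adjust_maps(y + 7.0, lab)
        for k in a:
            np.testing.assert_allclose(a[k], b[k], atol=1e-10)

    def test_condition_difference_preserved_when_balanced(self):
        rng = np.random.default_rng(10)
        lab = full_labels(n_subjects=2, per_cell=3)
        y = rng.standard_normal((len(lab), 4))
        adj = adjust_maps(y, lab, by=("stimulus_type",))
        eyes = (lab.stimulus_type == "eyes").to_numpy()
        raw_diff = y[eyes].mean(axis=0) - y[~eyes].mean(axis=0)
        adj_diff = adj[("eyes",)] - adj[("mosaic",)]
        np.testing.assert_allclose(adj_diff, raw_diff, atol=1e-8)


class TestEffectSizeWindow:
    TIMES = np.arange(0.0, 501.0, 5.0)
    FREQS = np.arange(4.0, 61.0, 1.0)

    def test_constant_map(self):
        v = np.full((101, 57), 3.3)
        assert effect_size_window(v, self.TIMES, self.FREQS, (200.0, 44.0)) == pytest.approx(3.3)

    def test_corner_clipping(self):
        v = np.arange(101 * 57, dtype=float).reshape(101, 57)
        got = effect_size_window(v, self.TIMES, self.FREQS, (0.0, 4.0))
        # clipped quadrant: times 0..15 ms (4 cells) x freqs 4..7 Hz (4 cells)
        expected = v[:4, :4].mean()
        assert got == pytest.approx(expected)

    def test_hand_computed_fixture(self):
        times = np.array([0.0, 15.0, 30.0])
        freqs = np.array([40.0, 43.0, 46.0])
        v = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        # |t| <= 15 keeps rows at 0 and 15 ms; |f - 40| <= 3 keeps 40 and 43 Hz
        got = effect_size_window(v, times, freqs, (0.0, 40.0))
        assert got == pytest.approx(np.mean([1, 2, 4, 5]))

    def test_focus_outside_map(self):
        with pytest.raises(ValueError):
            effect_size_window(np.zeros((101, 57)), self.TIMES, self.FREQS, (900.0, 44.0))
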