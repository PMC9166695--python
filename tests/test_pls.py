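"""PLS-SVD chain: stages, inference machinery, selection and contributions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import continuous_outcomes
from neuropls.pls import (
    BootstrapResult,
    PLSConfig,
    PLSCorrelation,
    bootstrap_saliences,
    modality_contribution,
    permutation_test,
    pls_svd,
    residualize,
    run_analysis,
    select_top,
    zscore_columns,
)


class TestResidualize:
    def test_matches_hat_matrix(self, rng):
        X = rng.standard_normal((35, 4))
        C = rng.standard_normal((35, 3))
        D = np.column_stack([np.ones(35), C])
        H = D @ np.linalg.inv(D.T @ D) @ D.T
        np.testing.assert_allclose(residualize(X, C), (np.eye(35) - H) @ X, atol=1e-10)

    def test_column_equal_to_covariate_vanishes(self, rng):
        C = rng.standard_normal((20, 3))
        X = C[:, [0]] * 2.0 + 5.0
        np.testing.assert_allclose(residualize(X, C), 0.0, atol=1e-10)

    def test_orthogonal_column_only_centered(self, rng):
        n = 40
        C = rng.standard_normal((n, 2))
        x = rng.standard_normal(n)
        # orthogonalize x against [1, C] so only centering should act
        D = np.column_stack([np.ones(n), C])
        x = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
        out = residualize(x[:, None] + 3.0, C)
        np.testing.assert_allclose(out[:, 0], x, atol=1e-10)

    def test_collinear_covariates_named(self, rng):
        C = rng.standard_normal((20, 2))
        C = np.column_stack([C, C[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.standard_normal((20, 3)), C)

    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.standard_normal((30, 6))
        C = rng.standard_normal((30, 3))
        R = residualize(X, C)
        np.testing.assert_allclose(C.T @ R, 0.0, atol=1e-9)


class TestZscore:
    def test_small_example(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_already_standardized_unchanged(self, rng):
        x = rng.standard_normal((50, 3))
        z = zscore_columns(x)
        np.testing.assert_allclose(zscore_columns(z), z, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_columns(np.column_stack([np.arange(5.0), np.full(5, 2.0)]))


class TestPlsSvd:
    def test_diagonal_cross_covariance(self, rng):
        # construct blocks whose cross-block matrix is exactly diag(3, 1)
        n = 10
        Q, _ = np.linalg.qr(rng.standard_normal((n, 2)))
        X = Q
        Y = Q @ np.diag([3.0, 1.0]) * (n - 1)
        fit = pls_svd(X, Y)
        np.testing.assert_allclose(fit.singular_values, [3.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(fit.covariance_explained, [0.9, 0.1], atol=1e-10)

    def test_identical_blocks_pair_scores(self, rng):
        n = 30
        Q, _ = np.linalg.qr(rng.standard_normal((n, 5)))
        fit = pls_svd(Q, Q)
        np.testing.assert_allclose(fit.x_scores, fit.y_scores, atol=1e-9)

    def test_singular_values_match_eigendecomposition(self, rng):
        X = zscore_columns(rng.standard_normal((35, 40)))
        Y = zscore_columns(rng.standard_normal((35, 5)))
        fit = pls_svd(X, Y)
        R = Y.T @ X / 34
        eigvals = np.linalg.eigvalsh(R @ R.T)[::-1]
        np.testing.assert_allclose(fit.singular_values, np.sqrt(eigvals), atol=1e-8)

    def test_orthonormal_saliences(self, rng):
        X = zscore_columns(rng.standard_normal((35, 40)))
        Y = zscore_columns(rng.standard_normal((35, 5)))
        fit = pls_svd(X, Y)
        np.testing.assert_allclose(
            fit.imaging_saliences.T @ fit.imaging_saliences, np.eye(5), atol=1e-10
        )
        np.testing.assert_allclose(
            fit.clinical_saliences.T @ fit.clinical_saliences, np.eye(5), atol=1e-10
        )

    def test_covariance_explained_sums_to_one(self, rng):
        X = zscore_columns(rng.standard_normal((20, 8)))
        Y = zscore_columns(rng.standard_normal((20, 5)))
        fit = pls_svd(X, Y)
        assert fit.covariance_explained.sum() == pytest.approx(1.0)
        assert (np.diff(fit.singular_values) <= 1e-12).all()

    def test_scale_equivariance_through_zscore(self, rng):
        raw_X = rng.standard_normal((30, 10))
        raw_Y = rng.standard_normal((30, 5))
        scales = rng.uniform(0.1, 10, size=10)
        f1 = pls_svd(zscore_columns(raw_X), zscore_columns(raw_Y))
        f2 = pls_svd(zscore_columns(raw_X * scales), zscore_columns(raw_Y))
        np.testing.assert_allclose(
            f1.imaging_saliences, f2.imaging_saliences, atol=1e-9
        )

    def test_sign_coherence_under_column_flip(self, rng):
        X = zscore_columns(rng.standard_normal((30, 10)))
        Y = zscore_columns(rng.standard_normal((30, 5)))
        f1 = pls_svd(X, Y)
        Y2 = Y.copy()
        Y2[:, 2] = -Y2[:, 2]
        f2 = pls_svd(X, Y2)
        flip = np.ones(5)
        flip[2] = -1.0
        for k in range(5):
            # equality up to the global per-component sign convention
            direct = np.allclose(f2.clinical_saliences[:, k],
                                 flip * f1.clinical_saliences[:, k], atol=1e-9)
            flipped = np.allclose(f2.clinical_saliences[:, k],
                                  -flip * f1.clinical_saliences[:, k], atol=1e-9)
            assert direct or flipped

    def test_subject_mismatch_and_zero_block_rejected(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            pls_svd(rng.standard_normal((10, 3)), rng.standard_normal((9, 3)))
        with pytest.raises(ValueError, match="zero"):
            pls_svd(np.zeros((10, 3)), rng.standard_normal((10, 3)))


class TestPermutation:
    def test_determinism(self, rng):
        X = rng.standard_normal((35, 30))
        Y = rng.standard_normal((35, 5))
        cfg = PLSConfig(n_permutations=100, seed=9)
        p1 = permutation_test(X, Y, None, cfg)
        p2 = permutation_test(X, Y, None, cfg)
        np.testing.assert_array_equal(p1.fwe_p, p2.fwe_p)
        np.testing.assert_array_equal(
            p1.null_singular_values, p2.null_singular_values
        )

    def test_perfect_association_attains_minimum_p(self, rng):
        X = rng.standard_normal((35, 20))
        Y = X[:, :5].copy()
        res = permutation_test(X, Y, None, PLSConfig(n_permutations=100, seed=0))
        assert res.fwe_p[0] == pytest.approx(1 / 101)

    def test_p_values_bounded_and_monotone(self, rng):
        X = rng.standard_normal((35, 30))
        Y = rng.standard_normal((35, 5))
        res = permutation_test(X, Y, None, PLSConfig(n_permutations=100, seed=1))
        assert (res.fwe_p >= 1 / 101).all() and (res.fwe_p <= 1.0).all()
        assert (np.diff(res.fwe_p) >= 0).all()  # max-statistic rule

    def test_observed_statistic_unchanged_by_basis(self, rng):
        # the covariate-orthogonal permutation basis must leave the observed
        # singular values exactly as computed on the residualized blocks
        X = rng.standard_normal((35, 30))
        Y = rng.standard_normal((35, 5))
        C = rng.standard_normal((35, 3))
        from scipy.linalg import null_space

        from neuropls.pls import _prepare_blocks

        Xs, Ys = _prepare_blocks(X, Y, C)
        Q = null_space(np.column_stack([np.ones(35), C]).T)
        s_direct = np.linalg.svd(Ys.T @ Xs / 34, compute_uv=False)
        s_basis = np.linalg.svd((Q.T @ Ys).T @ (Q.T @ Xs) / 34, compute_uv=False)
        np.testing.assert_allclose(s_direct, s_basis, atol=1e-10)

    def test_raw_mode_runs_and_is_deterministic(self, rng):
        X = rng.standard_normal((35, 30))
        Y = rng.standard_normal((35, 5))
        C = rng.standard_normal((35, 3))
        cfg = PLSConfig(n_permutations=50, seed=3, permute="raw")
        p1 = permutation_test(X, Y, C, cfg)
        p2 = permutation_test(X, Y, C, cfg)
        np.testing.assert_array_equal(p1.fwe_p, p2.fwe_p)


class TestBootstrap:
    def test_planted_feature_robust_and_zero_feature_not(self, small_cohort):
        outcomes = continuous_outcomes(small_cohort)
        model = PLSCorrelation.from_tables(
            small_cohort.features_baseline, outcomes, small_cohort.covariates
        )
        res = model.fit(PLSConfig(n_permutations=50, n_bootstrap=200, seed=0))
        u = small_cohort.truth["imaging_saliences"][:, 0]
        boot = res.bootstrap
        strongest = np.argmax(np.abs(u))
        assert boot.imaging_robust[strongest, 0]
        assert np.abs(boot.imaging_ratio[strongest, 0]) > 2.0
        zero = np.flatnonzero(u == 0)
        # most planted-zero features should have CIs crossing zero
        assert (~boot.imaging_robust[zero, 0]).mean() > 0.75

    def test_robust_flag_equals_ci_excluding_zero(self, small_cohort):
        outcomes = continuous_outcomes(small_cohort)
        model = PLSCorrelation.from_tables(
            small_cohort.features_baseline, outcomes, small_cohort.covariates
        )
        res = model.fit(PLSConfig(n_permutations=10, n_bootstrap=80, seed=1))
        lo, hi = res.bootstrap.imaging_ci
        np.testing.assert_array_equal(
            res.bootstrap.imaging_robust, (lo * hi) > 0
        )

    def test_se_stability_when_b_doubles(self, rng):
        X = rng.standard_normal((60, 25))
        Y = X[:, :5] * 0.8 + rng.standard_normal((60, 5)) * 0.6
        Xs, Ys = zscore_columns(X), zscore_columns(Y)
        fit = pls_svd(Xs, Ys)
        r1 = bootstrap_saliences(
            X, Y, None, fit, PLSConfig(n_bootstrap=300, seed=5)
        )
        r2 = bootstrap_saliences(
            X, Y, None, fit, PLSConfig(n_bootstrap=600, seed=6)
        )
        se1 = fit.clinical_saliences / r1.clinical_ratio
        se2 = fit.clinical_saliences / r2.clinical_ratio
        np.testing.assert_allclose(se1, se2, rtol=0.5, atol=0.02)


class TestSelection:
    def _boot(self, ratios):
        r = np.asarray(ratios, float)[:, None]
        lo = r - 0.5
        hi = r + 0.5
        return BootstrapResult(
            imaging_ratio=r, clinical_ratio=np.zeros((5, 1)),
            imaging_ci=(lo, hi), clinical_ci=(np.zeros((5, 1)), np.zeros((5, 1))),
            imaging_robust=(lo * hi) > 0, clinical_robust=np.zeros((5, 1), bool),
            n_degenerate_resamples=0,
        )

    def test_count_is_ceiling_of_fraction(self, rng):
        boot = self._boot(rng.normal(5, 1, size=416))
        sel = select_top(boot, fraction=0.05, require_robust=False)
        assert len(sel) == 21  # ceil(416 * 0.05)

    def test_all_equal_ratios_selected_by_column_order(self):
        boot = self._boot(np.full(10, 3.0))
        with pytest.warns(UserWarning, match="tie"):
            sel = select_top(boot, fraction=0.3, require_robust=False)
        np.testing.assert_array_equal(sel, [0, 1, 2])

    def test_fraction_one_selects_all(self):
        boot = self._boot(np.arange(1.0, 9.0))
        sel = select_top(boot, fraction=1.0, require_robust=False)
        assert len(sel) == 8

    def test_robust_intersection(self):
        ratios = np.array([5.0, 4.0, 0.2, 3.0])
        boot = self._boot(ratios)  # feature 2 has CI crossing zero
        sel = select_top(boot, fraction=1.0, require_robust=True)
        np.testing.assert_array_equal(sel, [0, 1, 3])


class TestModalityContribution:
    def _boot_with(self, ratios):
        r = np.asarray(ratios, float)[:, None]
        z = np.zeros((5, 1))
        return BootstrapResult(
            imaging_ratio=r, clinical_ratio=z, imaging_ci=(r, r),
            clinical_ci=(z, z), imaging_robust=np.ones_like(r, bool),
            clinical_robust=np.zeros((5, 1), bool), n_degenerate_resamples=0,
        )

    def test_hand_set_ratios_normalize(self):
        # within-modality |ratio| sums {6, 0, 2.1, 1.8} -> {0.61, 0, 0.21, 0.18}
        ratios = [4.0, 2.0, 0.7, 2.1, 1.8]
        labels = ["fALFF", "fALFF", "ReHo", "GM_atrophy", "GM_density"]
        boot = self._boot_with(ratios)
        selection = np.array([0, 1, 3, 4])  # ReHo not selected
        out = modality_contribution(
            boot, selection, labels,
            modalities=("fALFF", "ReHo", "GM_atrophy", "GM_density"),
        )
        np.testing.assert_allclose(
            out.values.round(2), [0.61, 0.0, 0.21, 0.18], atol=0.005
        )
        assert out.sum() == pytest.approx(1.0)

    def test_single_modality_takes_all(self):
        boot = self._boot_with([1.0, 2.0, 3.0])
        out = modality_contribution(
            boot, np.array([0, 1]), ["fALFF", "fALFF", "ReHo"],
            modalities=("fALFF", "ReHo"),
        )
        assert out["fALFF"] == pytest.approx(1.0)
        assert out["ReHo"] == 0.0

    def test_equal_totals_split_evenly(self):
        boot = self._boot_with([2.0, 1.0, 3.0])
        out = modality_contribution(
            boot, np.array([0, 1, 2]), ["a", "a", "b"], modalities=("a", "b")
        )
        np.testing.assert_allclose(out.values, [0.5, 0.5])

    def test_empty_selection_rejected(self):
        boot = self._boot_with([1.0])
        with pytest.raises(ValueError, match="empty"):
            modality_contribution(boot, np.array([], int), ["a"])


class TestRunAnalysis:
    def test_planted_cohort_has_one_significant_component(self, small_cohort):
        outcomes = continuous_outcomes(small_cohort)
        res = run_analysis(
            small_cohort.features_baseline, outcomes, small_cohort.covariates,
            PLSConfig(n_permutations=200, n_bootstrap=100, seed=2),
        )
        assert 0 in res.significant_components
        assert res.covariance_explained[0] > 0.3

    def test_changes_mode_identical_visits_raises_constant_column(self, small_cohort):
        from neuropls.features import compute_changes

        changes = compute_changes(
            small_cohort.features_baseline, small_cohort.features_baseline
        )
        outcomes = continuous_outcomes(small_cohort)
        with pytest.raises(ValueError, match="constant"):
            run_analysis(
                changes, outcomes, small_cohort.covariates,
                PLSConfig(n_permutations=10, n_bootstrap=10), mode="changes",
            )

    def test_results_round_trip_to_directory(self, tmp_path, small_cohort):
        outcomes = continuous_outcomes(small_cohort)
        res = run_analysis(
            small_cohort.features_baseline, outcomes, small_cohort.covariates,
            PLSConfig(n_permutations=20, n_bootstrap=20, seed=0),
        )
        out = res.save(tmp_path / "pls")
        for name in (
            "saliences.csv", "bootstrap_ratios.csv", "ci.csv", "permutation.csv",
            "components.csv", "contributions.csv", "latent_scores.csv",
            "manifest.json",
        ):
            assert (out / name).exists(), name
        comp = pd.read_csv(out / "components.csv", index_col=0)
        np.testing.assert_allclose(
            comp["singular_value"].values, res.singular_values, atol=1e-12
        )

    def test_score_scatter_written(self, tmp_path, small_cohort):
        outcomes = continuous_outcomes(small_cohort)
        res = run_analysis(
            small_cohort.features_baseline, outcomes, small_cohort.covariates,
            PLSConfig(n_permutations=10, n_bootstrap=10, seed=0),
        )
        path = tmp_path / "scores.png"
        res.plot_scores(color=outcomes["updrs3_total"], path=path)
        assert path.exists() and path.stat().st_size > 0

    def test_summary_text_reports_components(self, small_cohort):
        outcomes = continuous_outcomes(small_cohort)
        res = run_analysis(
            small_cohort.features_baseline, outcomes, small_cohort.covariates,
            PLSConfig(n_permutations=20, n_bootstrap=20, seed=0),
        )
        text = res.summary()
        assert "LV" in text and "FWE p" in text
        assert "updrs3_total" in text
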