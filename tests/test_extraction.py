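"""Extraction: GLM oracle checks, supertrials, noise normalization, smoothing,
PCA retention."""

import numpy as np
import pytest

from ctt import SimSpec, ValidationError, estimate_noise_model, fit_run_glm, \
    generate_truth, make_supertrials, noise_normalize, reduce_dimensions, \
    simulate_localizer, smooth_temporal
from conftest import make_patternset


class TestRunGlm:
    def test_noiseless_recovery(self, rng):
        X = rng.standard_normal((30, 3))
        B0 = rng.standard_normal((3, 7))
        res = fit_run_glm(X @ B0, X)
        assert np.allclose(res.betas, B0, atol=1e-10)
        assert np.allclose(res.residuals, 0, atol=1e-10)

    def test_intercept_only_gives_column_means(self, rng):
        Y = rng.standard_normal((20, 4))
        res = fit_run_glm(Y, np.ones((20, 1)))
        assert np.allclose(res.betas[0], Y.mean(axis=0), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        # independent oracle: solve X'X b = X'y directly
        X = rng.standard_normal((6, 2))
        Y = rng.standard_normal((6, 3))
        res = fit_run_glm(Y, X)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(res.betas, oracle, atol=1e-10)
        # t values: beta / sqrt(sigma^2 * diag((X'X)^-1))
        resid = Y - X @ oracle
        s2 = (resid**2).sum(axis=0) / res.dof
        se = np.sqrt(np.outer(np.diag(np.linalg.inv(X.T @ X)), s2))
        assert np.allclose(res.t_values, oracle / se, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 6))
        res = fit_run_glm(Y, X)
        rel = np.abs(X.T @ res.residuals).max() / np.abs(Y).max()
        assert rel < 1e-8

    def test_rank_deficient_design_names_columns(self, rng):
        X = rng.standard_normal((10, 2))
        X3 = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_run_glm(rng.standard_normal((10, 4)), X3)

    def test_too_few_timepoints(self, rng):
        with pytest.raises(ValidationError, match="timepoints"):
            fit_run_glm(rng.standard_normal((3, 2)), rng.standard_normal((3, 3)))


class TestSupertrials:
    def test_k1_identity(self, small_datasets):
        _, loc, _ = small_datasets
        out = make_supertrials(loc, 1)
        assert np.array_equal(out.patterns, loc.patterns)
        assert np.array_equal(out.condition_labels, loc.condition_labels)

    def test_full_cell_average(self, rng):
        ps = make_patternset(rng.standard_normal((8, 5)),
                             conditions=["a"] * 4 + ["b"] * 4)
        out = make_supertrials(ps, 4)
        assert out.n_observations == 2
        for cond in ("a", "b"):
            got = out.patterns[out.condition_labels == cond][0]
            want = ps.patterns[ps.condition_labels == cond].mean(axis=0)
            assert np.allclose(got, want, atol=1e-12)

    def test_permuting_input_keeps_full_cell_mean(self, rng):
        ps = make_patternset(rng.standard_normal((6, 4)), conditions=["a"] * 6)
        perm = rng.permutation(6)
        ps2 = ps.take_observations(perm)
        a = make_supertrials(ps, 6).patterns
        b = make_supertrials(ps2, 6).patterns
        assert np.allclose(a, b, atol=1e-12)

    def test_remainder_discarded_and_small_cells_error(self, rng):
        ps = make_patternset(rng.standard_normal((10, 3)), conditions=["a"] * 10)
        out = make_supertrials(ps, 4)
        assert out.n_observations == 2  # 10 // 4 groups
        with pytest.raises(ValidationError, match="fewer than"):
            make_supertrials(ps, 11)

    def test_variance_reduction_quarter(self):
        # i.i.d. noise trials averaged in groups of 4: variance ~ sigma^2/4
        rng = np.random.default_rng(8)
        sigma = 1.0
        ps = make_patternset(rng.normal(0, sigma, (4000, 8)),
                             conditions=["a"] * 4000)
        out = make_supertrials(ps, 4, seed=0)
        ratio = out.patterns.var(ddof=1) / sigma**2
        assert abs(ratio - 0.25) < 0.025

    def test_deterministic_under_seed(self, small_datasets):
        _, loc, _ = small_datasets
        a = make_supertrials(loc, 2, seed=5)
        b = make_supertrials(loc, 2, seed=5)
        assert np.array_equal(a.patterns, b.patterns)


class TestNoiseNormalize:
    def test_unit_sd_is_identity(self, rng):
        ps = make_patternset(rng.standard_normal((6, 4)))
        out = noise_normalize(ps, "univariate", residual_sd=np.ones(4))
        assert np.array_equal(out.patterns, ps.patterns)
        assert out is not ps

    def test_zero_sd_errors(self, rng):
        ps = make_patternset(rng.standard_normal((6, 4)))
        sd = np.array([1.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="zero residual SD"):
            noise_normalize(ps, "univariate", residual_sd=sd)

    def test_full_shrinkage_equals_univariate_exactly(self, rng):
        resid = rng.standard_normal((200, 6))
        ps = make_patternset(rng.standard_normal((10, 6)))
        noise = estimate_noise_model(resid, dof=199, shrinkage=1.0)
        multi = noise_normalize(ps, "multivariate", noise=noise)
        sd = np.sqrt(np.diag(noise.covariance))
        uni = noise_normalize(ps, "univariate", residual_sd=sd)
        assert np.array_equal(multi.patterns, uni.patterns)

    def test_whitening_decorrelates(self):
        # residuals with rho=0.3 equicorrelation: whitened covariance ~ I
        rng = np.random.default_rng(11)
        V, n = 10, 5000
        rho = 0.3
        cov = (1 - rho) * np.eye(V) + rho
        L = np.linalg.cholesky(cov)
        resid = rng.standard_normal((n, V)) @ L.T
        noise = estimate_noise_model(resid, shrinkage=0.0)
        white = resid @ noise.whitener
        emp = np.cov(white.T)
        assert np.linalg.norm(emp - np.eye(V)) < 0.1 * V

    def test_whitener_inverts_covariance(self, rng):
        resid = rng.standard_normal((500, 5))
        noise = estimate_noise_model(resid)
        recon = noise.whitener @ noise.covariance @ noise.whitener.T
        assert np.allclose(recon, np.eye(5), atol=1e-8)

    def test_too_few_timepoints_error(self, rng):
        with pytest.raises(ValidationError, match="at least"):
            estimate_noise_model(rng.standard_normal((5, 4)))


class TestSmoothing:
    def _epoch_ps(self, values):
        values = np.asarray(values, dtype=float)[:, None]
        n = len(values)
        return make_patternset(values, conditions=["a"] * n,
                               time_bins=np.arange(n),
                               trial_ids=np.zeros(n, dtype=int))

    def test_w1_identity(self):
        ps = self._epoch_ps([0, 4, 0, 4])
        out = smooth_temporal(ps, 1)
        assert np.array_equal(out.patterns, ps.patterns)

    def test_constant_trial_fixed_point(self):
        ps = self._epoch_ps([3, 3, 3, 3, 3])
        out = smooth_temporal(ps, 3)
        assert np.allclose(out.patterns, 3.0, atol=0)

    def test_truncated_window_arithmetic(self):
        ps = self._epoch_ps([0, 4, 0, 4])
        out = smooth_temporal(ps, 3)
        assert np.allclose(out.patterns.ravel(), [2, 4 / 3, 8 / 3, 2])

    def test_window_validation(self):
        ps = self._epoch_ps([0, 1, 2])
        with pytest.raises(ValidationError):
            smooth_temporal(ps, 2)  # even
        with pytest.raises(ValidationError):
            smooth_temporal(ps, 5)  # exceeds bins


class TestPca:
    def test_full_retention_keeps_nonzero_components(self, rng):
        X = rng.standard_normal((20, 5))
        ps = make_patternset(X)
        (out,), pca = reduce_dimensions(ps, [ps], 1.0)
        assert pca.n_components_ == 5
        assert out.space == "component"

    def test_rank1_data_one_component(self, rng):
        u = rng.standard_normal((30, 1))
        v = rng.standard_normal((1, 8))
        ps = make_patternset(u @ v)
        (_,), pca = reduce_dimensions(ps, [ps], 0.5)
        assert pca.n_components_ == 1

    def test_retained_count_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((60, 12)) * np.linspace(3, 0.2, 12)
        ps = make_patternset(X)
        (_,), pca = reduce_dimensions(ps, [ps], 0.99)
        # oracle: full eigendecomposition of the centered covariance
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        d_oracle = int(np.searchsorted(cum, 0.99 - 1e-12) + 1)
        assert pca.n_components_ == d_oracle

    def test_projection_shared_between_sets(self, rng):
        train = make_patternset(rng.standard_normal((30, 6)))
        other = make_patternset(rng.standard_normal((10, 6)))
        (out_train, out_other), pca = reduce_dimensions(train, [train, other], 0.9)
        assert out_other.n_units == out_train.n_units == pca.n_components_

    def test_fraction_validation(self, rng):
        ps = make_patternset(rng.standard_normal((5, 3)))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                reduce_dimensions(ps, [ps], bad)

    def test_inputs_not_mutated(self, small_datasets):
        _, loc, _ = small_datasets
        before = loc.patterns.copy()
        make_supertrials(loc, 2, seed=0)
        noise_normalize(loc, "univariate", residual_sd=np.full(loc.n_units, 2.0))
        assert np.array_equal(loc.patterns, before)
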