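"""Tracking metrics: similarity, cross-validated estimators, regression
partitioning, classifier decision values, relative indexes."""

import numpy as np
import pytest

from ctt import CTTError, SimSpec, TemplateSet, ValidationError, \
    classifier_tracking, crossvalidated_index, estimate_noise_model, \
    estimate_templates, generate_truth, regression_partition, \
    relative_activation, similarity_index, simulate_localizer, \
    simulate_main_task
from ctt.extraction import NoiseModel
from conftest import make_patternset


def make_templates(matrix, names=None, **kw):
    matrix = np.asarray(matrix, dtype=float)
    return TemplateSet(templates=matrix,
                       condition_names=names or [f"t{i}" for i in
                                                 range(matrix.shape[0])],
                       unit_ids=np.arange(matrix.shape[1]), **kw)


class TestSimilarityIndex:
    def test_identical_pattern_r1_d0(self, rng):
        t = rng.standard_normal(20)
        ts = make_templates(t[None, :])
        ps = make_patternset(t[None, :], conditions=["x"])
        assert similarity_index(ps, ts, "pearson").indexes[0, 0] == pytest.approx(1.0)
        assert similarity_index(ps, ts, "euclidean").indexes[0, 0] == 0.0

    def test_anticorrelated_patterns(self):
        ts = make_templates([[1, 0, 1, 0]])
        ps = make_patternset([[0, 1, 0, 1]], conditions=["x"])
        assert similarity_index(ps, ts, "pearson").indexes[0, 0] == pytest.approx(-1.0)

    def test_345_triangle(self):
        ts = make_templates([[0.0, 0.0]])
        ps = make_patternset([[3.0, 4.0]], conditions=["x"])
        assert similarity_index(ps, ts, "euclidean").indexes[0, 0] == pytest.approx(5.0)

    def test_sq_euclidean_is_square_of_euclidean(self, small_datasets):
        _, loc, main = small_datasets
        ts = estimate_templates(loc)
        d = similarity_index(main, ts, "euclidean").indexes
        d2 = similarity_index(main, ts, "sq_euclidean").indexes
        assert np.array_equal(d2, d**2)

    def test_fisher_z_is_arctanh_of_r(self, small_datasets):
        _, loc, main = small_datasets
        ts = estimate_templates(loc)
        r = similarity_index(main, ts, "pearson").indexes
        z = similarity_index(main, ts, "fisher_z").indexes
        assert np.allclose(z, np.arctanh(r), atol=1e-12)

    def test_affine_rescaling_invariance_contrast(self, rng):
        # correlations survive per-pattern affine rescaling; distances do not
        t = rng.standard_normal(30)
        ts = make_templates(t[None, :])
        y = t + rng.standard_normal(30) * 0.3
        ps1 = make_patternset(y[None, :], conditions=["x"])
        ps2 = make_patternset((2.5 * y + 7)[None, :], conditions=["x"])
        r1 = similarity_index(ps1, ts, "pearson").indexes[0, 0]
        r2 = similarity_index(ps2, ts, "pearson").indexes[0, 0]
        assert r1 == pytest.approx(r2, abs=1e-12)
        d1 = similarity_index(ps1, ts, "euclidean").indexes[0, 0]
        d2 = similarity_index(ps2, ts, "euclidean").indexes[0, 0]
        assert d2 > d1

    def test_zero_variance_errors(self, rng):
        ts = make_templates(rng.standard_normal((1, 4)))
        flat = make_patternset(np.ones((1, 4)), conditions=["x"])
        with pytest.raises(ValidationError, match="zero-variance"):
            similarity_index(flat, ts, "pearson")

    def test_support_mismatch_errors(self, rng):
        ts = make_templates(rng.standard_normal((1, 4)))
        ps = make_patternset(rng.standard_normal((2, 5)))
        with pytest.raises(ValidationError, match="support"):
            similarity_index(ps, ts)


class TestCrossValidatedIndex:
    def _noiseless(self, rng, n_chunks=3):
        t = rng.standard_normal((2, 10))
        ts = make_templates(t, names=["a", "b"])
        pats = np.tile(t, (n_chunks, 1))
        ps = make_patternset(pats,
                             conditions=["a", "b"] * n_chunks,
                             runs=np.repeat(np.arange(n_chunks), 2))
        return ts, ps

    def test_zero_noise_fixed_point(self, rng):
        ts, ps = self._noiseless(rng)
        res = crossvalidated_index(ts, ps, "cv_sq_euclidean")
        own = [res.indexes[i, i] for i in range(2)]
        assert np.allclose(own, 0, atol=1e-18)

    def test_identity_whitener_matches_cv_sq_euclidean(self, small_datasets):
        _, loc, main = small_datasets
        ts = estimate_templates(loc)
        V = main.n_units
        noise = NoiseModel(covariance=np.eye(V), shrinkage=0.0,
                           whitener=np.eye(V))
        a = crossvalidated_index(ts, main, "cv_sq_euclidean").indexes
        b = crossvalidated_index(ts, main, "mahalanobis_cv", noise=noise).indexes
        assert np.allclose(a, b, atol=1e-10)

    def test_cv_correlation_noiseless_is_one(self, rng):
        ts, ps = self._noiseless(rng)
        res = crossvalidated_index(ts, ps, "cv_correlation")
        assert np.allclose(np.diag(res.indexes), 1.0, atol=1e-12)

    def test_single_chunk_errors_with_guidance(self, rng):
        t = rng.standard_normal((2, 6))
        ts = make_templates(t, names=["a", "b"])
        ps = make_patternset(np.tile(t, (2, 1)), conditions=["a", "b"] * 2,
                             runs=np.zeros(4, dtype=int))
        with pytest.raises(CTTError, match="chunks"):
            crossvalidated_index(ts, ps)

    def test_mahalanobis_requires_noise_model(self, small_datasets):
        _, loc, main = small_datasets
        ts = estimate_templates(loc)
        with pytest.raises(ValidationError, match="NoiseModel"):
            crossvalidated_index(ts, main, "mahalanobis_cv")

    def test_naive_biased_cv_centered_at_zero(self):
        """Same true pattern for template and task: the naive squared distance
        sits near 2*V*sigma^2 while the crossed cv estimator is near 0."""
        reps, V, sigma = 120, 80, 0.5
        naive, cv = [], []
        for r in range(reps):
            spec = SimSpec(n_units=V, n_conditions=2, noise_sd=sigma,
                           n_localizer_trials_per_condition=2,
                           n_runs_localizer=2,
                           n_main_trials_per_condition=8, n_chunks_main=8,
                           seed=9000 + r)
            truth = generate_truth(spec)
            loc = simulate_localizer(truth, spec)
            main = simulate_main_task(truth, spec)
            ts = estimate_templates(loc, keep_runwise=True)
            y = main.patterns[main.condition_labels == "cond0"]
            T_runs = ts.runwise_estimates[:, 0, :]
            naive.append(((T_runs[:, None, :] - y[None, :, :]) ** 2)
                         .sum(axis=-1).mean())
            res = crossvalidated_index(ts, main, cross_template_runs=True)
            cv.append(res.indexes[res.observation_conditions.tolist().index("cond0"), 0])
        naive = np.mean(naive)
        cv = np.asarray(cv)
        analytic = 2 * V * sigma**2
        assert abs(naive / analytic - 1) < 0.1
        se = cv.std(ddof=1) / np.sqrt(reps)
        assert abs(cv.mean()) < 2 * se

    def test_negative_values_reported_not_clipped(self, small_datasets):
        _, loc, main = small_datasets
        ts = estimate_templates(loc, keep_runwise=True)
        res = crossvalidated_index(ts, main, cross_template_runs=True)
        assert res.metadata["n_negative"] == int((res.indexes < 0).sum())


class TestRegressionPartition:
    def test_orthogonal_noiseless_recovery(self):
        t1 = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0])
        t2 = np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0])
        ts = make_templates(np.vstack([t1, t2]), names=["a", "b"])
        y = 2 * t1 + 3 * t2
        ps = make_patternset(y[None, :], conditions=["x"])
        res = regression_partition(ps, ts)
        assert np.allclose(res.indexes[0], [2.0, 3.0], atol=1e-10)
        assert res.r_squared[0] == pytest.approx(1.0)

    def test_single_template_beta_and_sr(self, rng):
        t = rng.standard_normal(40)
        ts = make_templates(t[None, :], names=["a"])
        ps = make_patternset(t[None, :], conditions=["x"])
        res = regression_partition(ps, ts)
        assert res.indexes[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert res.semipartial_r[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_semipartial_matches_residualization_oracle(self, rng):
        # correlated templates; oracle: correlate y with t_k residualized
        # on the other templates
        T = rng.standard_normal((3, 60))
        T[1] += 0.7 * T[0]
        ts = make_templates(T, names=["a", "b", "c"])
        Y = rng.standard_normal((5, 60))
        ps = make_patternset(Y, conditions=["x"] * 5)
        res = regression_partition(ps, ts)
        Tc = (T - T.mean(axis=1, keepdims=True)).T
        Yc = (Y - Y.mean(axis=1, keepdims=True)).T
        for i in range(5):
            y = Yc[:, i]
            for k in range(3):
                others = np.delete(Tc, k, axis=1)
                proj = others @ np.linalg.lstsq(others, Tc[:, k], rcond=None)[0]
                resid_t = Tc[:, k] - proj
                oracle = (y @ resid_t) / (np.linalg.norm(y)
                                          * np.linalg.norm(resid_t))
                assert abs(abs(res.semipartial_r[i, k]) - abs(oracle)) < 1e-10
                if abs(oracle) > 1e-8:
                    assert np.sign(res.semipartial_r[i, k]) == np.sign(oracle)

    def test_collinear_templates_error_reports_condition_number(self, rng):
        t = rng.standard_normal(20)
        ts = make_templates(np.vstack([t, 2 * t]), names=["a", "b"])
        ps = make_patternset(rng.standard_normal((1, 20)), conditions=["x"])
        with pytest.raises(ValidationError, match="condition number"):
            regression_partition(ps, ts)

    def test_mean_betas_recover_weights(self):
        # main trials built as 2*t1 + 3*t2 + noise, orthogonal-ish templates
        spec = SimSpec(n_units=300, n_conditions=2, noise_sd=0.2,
                       n_main_trials_per_condition=40, n_chunks_main=4,
                       activation_weights={"mix": [2.0, 3.0]}, seed=31)
        truth = generate_truth(spec)
        main = simulate_main_task(truth, spec)
        ts = make_templates(truth.true_templates, names=["t1", "t2"])
        res = regression_partition(main, ts)
        mean_betas = res.indexes.mean(axis=0)
        assert np.all(np.abs(mean_betas / np.array([2.0, 3.0]) - 1) < 0.1)


class TestClassifierTracking:
    def _gaussian_templates(self, rng, delta=10.0, n=50, v=8, sigma=1.0):
        mu1 = np.zeros(v); mu1[0] = delta / 2
        mu2 = np.zeros(v); mu2[0] = -delta / 2
        ex = {"a": mu1 + rng.standard_normal((n, v)) * sigma,
              "b": mu2 + rng.standard_normal((n, v)) * sigma}
        ts = make_templates(np.vstack([mu1, mu2]), names=["a", "b"],
                            exemplars=ex)
        return ts, mu1, mu2

    def test_far_separated_classes_perfect_accuracy(self, rng):
        ts, mu1, mu2 = self._gaussian_templates(rng)
        test = np.vstack([mu1 + rng.standard_normal((50, 8)),
                          mu2 + rng.standard_normal((50, 8))])
        ps = make_patternset(test, conditions=["a"] * 50 + ["b"] * 50)
        res = classifier_tracking(ts, ps)
        assert res.metadata["accuracy"] == 1.0

    def test_midpoint_pattern_d_zero(self, rng):
        # the hyperplane midpoint is defined by the empirical class means
        ts, _, _ = self._gaussian_templates(rng, sigma=1.0)
        mid = 0.5 * (ts.exemplars["a"].mean(axis=0)
                     + ts.exemplars["b"].mean(axis=0))
        ps = make_patternset(mid[None, :], conditions=["?"])
        res = classifier_tracking(ts, ps, shrinkage=1.0)
        assert np.allclose(res.indexes[0], 0, atol=1e-8)

    def test_closed_form_discriminant_direction(self):
        # identity covariance, mu1=(1,0), mu2=(-1,0): w ~ (2,0); the pattern
        # (0.5, 7) lies on class-1 side
        rng = np.random.default_rng(0)
        ex = {"a": np.array([1.0, 0.0]) + rng.standard_normal((500, 2)),
              "b": np.array([-1.0, 0.0]) + rng.standard_normal((500, 2))}
        ts = make_templates(np.array([[1.0, 0.0], [-1.0, 0.0]]),
                            names=["a", "b"], exemplars=ex)
        ps = make_patternset(np.array([[0.5, 7.0]]), conditions=["?"])
        res = classifier_tracking(ts, ps, shrinkage=0.1)
        assert res.metadata["predicted_labels"][0] == "a"
        assert res.indexes[0, 0] > 0 > res.indexes[0, 1]

    def test_few_exemplars_error(self, rng):
        ts = make_templates(rng.standard_normal((2, 4)), names=["a", "b"],
                            exemplars={"a": rng.standard_normal((5, 4)),
                                       "b": rng.standard_normal((1, 4))})
        ps = make_patternset(rng.standard_normal((2, 4)))
        with pytest.raises(ValidationError, match="fewer than 2 exemplars"):
            classifier_tracking(ts, ps)

    def test_sign_agrees_with_argmax_correlation(self):
        spec = SimSpec(n_units=100, noise_sd=0.6, seed=77,
                       n_localizer_trials_per_condition=30,
                       n_main_trials_per_condition=30, n_chunks_main=2)
        truth = generate_truth(spec)
        loc = simulate_localizer(truth, spec)
        main = simulate_main_task(truth, spec)
        ts = estimate_templates(loc, keep_exemplars=True)
        d = classifier_tracking(ts, main)
        r = similarity_index(main, ts, "pearson")
        d_label = np.argmax(d.indexes, axis=1)
        r_label = np.argmax(r.indexes, axis=1)
        assert (d_label == r_label).mean() >= 0.95


class TestRelativeActivation:
    def _result(self, values, metric):
        from ctt.tracking import TrackingResult
        values = np.asarray(values, dtype=float)
        return TrackingResult(indexes=values, metric=metric,
                              condition_names=["t", "b"],
                              observation_conditions=np.array(["x"] * len(values)),
                              observation_runs=np.zeros(len(values), dtype=int))

    def test_equal_indexes_zero(self):
        tr = self._result([[0.4, 0.4]], "pearson")
        rel = relative_activation(tr, "t", "b")
        assert rel.relative_indexes[0, 0] == pytest.approx(0.0)

    def test_pearson_goes_through_fisher_z(self):
        tr = self._result([[0.5, 0.0]], "pearson")
        rel = relative_activation(tr, "t", "b")
        assert rel.relative_indexes[0, 0] == pytest.approx(np.arctanh(0.5))

    def test_distance_polarity_flipped(self):
        tr = self._result([[1.0, 3.0]], "euclidean")
        rel = relative_activation(tr, "t", "b")
        assert rel.relative_indexes[0, 0] == pytest.approx(2.0)

    def test_target_equals_baseline_errors(self):
        tr = self._result([[0.1, 0.2]], "pearson")
        with pytest.raises(ValidationError, match="differ"):
            relative_activation(tr, "t", "t")

    @pytest.mark.parametrize("metric,kind", [
        ("pearson", "similarity"), ("sq_euclidean", "similarity"),
        ("regression_beta", "regression"), ("classifier_d", "classifier")])
    def test_sign_recovery_across_metric_families(self, metric, kind):
        # target-active simulation: positive group-mean relative index
        spec = SimSpec(n_units=120, noise_sd=0.5, seed=55,
                       n_localizer_trials_per_condition=20,
                       n_main_trials_per_condition=20, n_chunks_main=2,
                       activation_weights={"cond0": [1.0, 0.0],
                                           "cond1": [1.0, 0.0]})
        truth = generate_truth(spec)
        loc = simulate_localizer(truth, spec)
        main = simulate_main_task(truth, spec)
        ts = estimate_templates(loc, keep_exemplars=True)
        if kind == "similarity":
            tr = similarity_index(main, ts, metric)
        elif kind == "regression":
            tr = regression_partition(main, ts)
        else:
            tr = classifier_tracking(ts, main)
        rel = relative_activation(tr, "cond0", "cond1")
        assert rel.relative_indexes.mean() > 0

    def test_tidy_frame_shape(self, small_datasets):
        _, loc, main = small_datasets
        ts = estimate_templates(loc)
        tr = similarity_index(main, ts)
        df = tr.to_frame()
        assert len(df) == main.n_observations * ts.n_conditions
        assert set(["observation", "condition", "template", "metric",
                    "value"]) <= set(df.columns)
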