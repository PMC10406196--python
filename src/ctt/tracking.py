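"""Template tracking: activation indexes of canonical templates in task data.

Every tracker returns a :class:`TrackingResult` whose ``indexes`` matrix
holds one activation index per (observation, template).  Metrics fall into
two polarity families: similarity-like metrics (correlation, Fisher z,
regression betas, semi-partial r, classifier decision values) where higher
means more active, and distance-like metrics (Euclidean, squared Euclidean
and their cross-validated versions, crossnobis/Mahalanobis) where lower
means more active.  :func:`relative_activation` folds the polarity so that
a positive relative index always reads "target template more active than
baseline template" — the interpretable quantity of the method.

Naive correlation and distance indexes are positively biased by noise
("less similar than they are") and have no meaningful zero; the
cross-validated estimators in :func:`crossvalidated_index` remove that bias
by multiplying difference vectors from independent main-task chunks, at the
price of possibly negative values (reported as-is, never clipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Any

import numpy as np
import pandas as pd

from .extraction import NoiseModel
from .patterns import CTTError, PatternSet, TemplateSet, ValidationError

__all__ = [
    "TrackingResult",
    "similarity_index",
    "crossvalidated_index",
    "regression_partition",
    "classifier_tracking",
    "relative_activation",
    "METRIC_POLARITY",
]

METRIC_POLARITY = {
    "pearson": "higher_is_more_active",
    "fisher_z": "higher_is_more_active",
    "cv_correlation": "higher_is_more_active",
    "regression_beta": "higher_is_more_active",
    "semipartial_r": "higher_is_more_active",
    "classifier_d": "higher_is_more_active",
    "euclidean": "lower_is_more_active",
    "sq_euclidean": "lower_is_more_active",
    "cv_sq_euclidean": "lower_is_more_active",
    "mahalanobis_cv": "lower_is_more_active",
}


@dataclass
class TrackingResult:
    """Per-observation x per-template activation indexes.

    ``indexes[i, k]`` is the activation index of template ``k`` in
    observation ``i``.  ``observation_*`` arrays carry the labels of the
    tracked PatternSet (or of the condition cells, for cross-validated
    estimators which collapse observations).
    """

    indexes: np.ndarray
    metric: str
    condition_names: list[str]
    observation_conditions: np.ndarray
    observation_runs: np.ndarray
    observation_time_bins: np.ndarray | None = None
    relative_indexes: np.ndarray | None = None
    relative_contrasts: list[tuple[str, str]] = field(default_factory=list)
    semipartial_r: np.ndarray | None = None
    r_squared: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indexes = np.asarray(self.indexes, dtype=float)
        if self.metric not in METRIC_POLARITY:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.indexes.ndim != 2 or self.indexes.shape[1] != len(self.condition_names):
            raise ValidationError("indexes must be observations x K")
        if not np.isfinite(self.indexes).all():
            raise ValidationError("indexes contain non-finite values")

    @property
    def polarity(self) -> str:
        return METRIC_POLARITY[self.metric]

    def column(self, condition: str) -> np.ndarray:
        try:
            k = self.condition_names.index(str(condition))
        except ValueError:
            raise ValidationError(f"no template column {condition!r}") from None
        return self.indexes[:, k]

    def relative(self, target: str, baseline: str) -> np.ndarray:
        """Relative index column (computing it on demand if needed)."""
        key = (str(target), str(baseline))
        if key in self.relative_contrasts:
            return self.relative_indexes[:, self.relative_contrasts.index(key)]
        return relative_activation(self, target, baseline).relative_indexes[:, -1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: observation, condition, run, template, value."""
        n, K = self.indexes.shape
        rows = {
            "observation": np.repeat(np.arange(n), K),
            "condition": np.repeat(self.observation_conditions, K),
            "run_or_chunk": np.repeat(self.observation_runs, K),
            "template": np.tile(np.asarray(self.condition_names), n),
            "metric": self.metric,
            "value": self.indexes.ravel(),
        }
        if self.observation_time_bins is not None:
            rows["time_bin"] = np.repeat(self.observation_time_bins, K)
        return pd.DataFrame(rows)


def _check_support(main: PatternSet, ts: TemplateSet) -> None:
    if not main.same_support(ts):
        raise ValidationError(
            "main PatternSet and TemplateSet do not share the same unit support "
            f"({main.n_units} vs {ts.n_units} units)")


def _center_rows(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def similarity_index(main: PatternSet, ts: TemplateSet, metric: str = "pearson"
                     ) -> TrackingResult:
    """Naive per-observation similarity to each template.

    ``pearson`` / ``fisher_z`` (arctanh of r) are invariant to per-pattern
    affine rescaling; ``euclidean`` / ``sq_euclidean`` are robust to
    correlation-distorting rescaling but grow with additive baseline shifts.
    """
    if metric not in ("pearson", "fisher_z", "euclidean", "sq_euclidean"):
        raise ValidationError(f"unsupported similarity metric {metric!r}")
    _check_support(main, ts)
    Y, T = main.patterns, ts.templates
    if metric in ("pearson", "fisher_z"):
        Yc, Tc = _center_rows(Y), _center_rows(T)
        ynorm = np.linalg.norm(Yc, axis=1)
        tnorm = np.linalg.norm(Tc, axis=1)
        bad_y = np.flatnonzero(ynorm == 0)
        if bad_y.size:
            raise ValidationError(
                f"zero-variance observations {bad_y[:10].tolist()} with a "
                "correlation metric")
        bad_t = [ts.condition_names[k] for k in np.flatnonzero(tnorm == 0)]
        if bad_t:
            raise ValidationError(
                f"zero-variance templates {bad_t} with a correlation metric")
        r = (Yc @ Tc.T) / np.outer(ynorm, tnorm)
        r = np.clip(r, -1.0, 1.0)
        if metric == "fisher_z":
            r = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
        values = r
    else:
        d = np.sqrt(((Y[:, None, :] - T[None, :, :]) ** 2).sum(axis=-1))
        # squared distances derive from the rooted ones so that
        # sq_euclidean == euclidean**2 holds bit-exactly
        values = d**2 if metric == "sq_euclidean" else d
    return TrackingResult(
        indexes=values,
        metric=metric,
        condition_names=list(ts.condition_names),
        observation_conditions=main.condition_labels,
        observation_runs=main.run_ids,
        observation_time_bins=main.time_bins,
        metadata={"tracker": "similarity_index"},
    )


def _chunk_means(main: PatternSet) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Mean pattern per (condition, chunk); returns conditions, chunks, means."""
    conds = main.conditions
    chunks = np.unique(main.run_ids)
    means = np.empty((len(conds), chunks.size, main.n_units))
    for i, cond in enumerate(conds):
        for j, c in enumerate(chunks):
            idx = np.flatnonzero((main.condition_labels == cond)
                                 & (main.run_ids == c))
            if idx.size == 0:
                raise ValidationError(
                    f"condition {cond!r} missing from chunk {c!r}; "
                    "cross-validated estimators need every condition in every chunk")
            means[i, j] = main.patterns[idx].mean(axis=0)
    return conds, chunks, means


def crossvalidated_index(ts: TemplateSet, main: PatternSet,
                         metric: str = "cv_sq_euclidean",
                         noise: NoiseModel | None = None,
                         cross_template_runs: bool = False) -> TrackingResult:
    """Cross-validated distance/correlation between templates and task data.

    The localizer templates stay fixed while the estimator iterates over
    ordered pairs of independent main-task chunks ``(c, c')``:

    * ``cv_sq_euclidean``: mean of ``(T - y_c)' (T - y_c')`` — unbiased for
      the true squared distance when the template is noise-free; the bias
      contributed by template noise is not corrected here unless
      ``cross_template_runs`` is set.
    * ``mahalanobis_cv`` (crossnobis): the same estimator after applying the
      multivariate noise whitener to templates and chunk means (requires a
      :class:`NoiseModel`).
    * ``cv_correlation``: mean over ordered chunk pairs of
      ``<T~, y~_c> / (||T~|| sqrt(<y~_c, y~_c'>))`` on centered vectors: the
      cross-chunk inner product in the denominator estimates the signal
      variance without its noise inflation.  Pairs whose cross-chunk inner
      product is not positive are dropped (count reported in metadata).

    With ``cross_template_runs`` (requires run-wise template estimates) the
    pair average additionally crosses template runs ``r != r'``, removing
    the template-noise bias as well:
    ``mean over (r != r', c != c') of (T_r - y_c)' (T_r' - y_c')``.

    Negative values are genuine outcomes of these unbiased estimators and
    are reported, never clipped; ``metadata['n_negative']`` counts them.
    One index is produced per main-task condition cell (observations are
    collapsed to chunk means).
    """
    if metric not in ("cv_sq_euclidean", "mahalanobis_cv", "cv_correlation"):
        raise ValidationError(f"unsupported cross-validated metric {metric!r}")
    _check_support(main, ts)
    if metric == "mahalanobis_cv" and noise is None:
        raise ValidationError("mahalanobis_cv requires a NoiseModel")
    conds, chunks, means = _chunk_means(main)
    if chunks.size < 2:
        raise CTTError(
            "cross-validated estimators need at least 2 independent main-task "
            "chunks; split the main paradigm into separate, equivalent runs")
    if cross_template_runs:
        if ts.runwise_estimates is None or ts.runwise_estimates.shape[0] < 2:
            raise ValidationError(
                "cross_template_runs requires run-wise template estimates "
                "from >= 2 localizer runs")
        T_stack = ts.runwise_estimates  # (R, K, V)
    else:
        T_stack = ts.templates[None, :, :]  # single fixed template "run"

    if metric == "mahalanobis_cv":
        W = noise.whitener
        if W.shape != (main.n_units, main.n_units):
            raise ValidationError("NoiseModel dimension must equal unit count")
        T_stack = T_stack @ W
        means = means @ W

    K = ts.n_conditions
    n_cells = len(conds)
    values = np.empty((n_cells, K))
    n_dropped = 0
    chunk_pairs = list(permutations(range(chunks.size), 2))
    R = T_stack.shape[0]
    if R == 1:
        run_pairs = [(0, 0)]
    else:
        run_pairs = list(permutations(range(R), 2))

    for i in range(n_cells):
        for k in range(K):
            acc, cnt = 0.0, 0
            if metric == "cv_correlation":
                Tc = T_stack[:, k, :] - T_stack[:, k, :].mean(axis=1, keepdims=True)
                Yc = means[i] - means[i].mean(axis=1, keepdims=True)
                for (r, rp) in run_pairs:
                    tnorm = np.sqrt(Tc[r] @ Tc[rp])
                    if not tnorm > 0:
                        continue
                    for (c, cp) in chunk_pairs:
                        cross = Yc[c] @ Yc[cp]
                        if cross <= 0:
                            n_dropped += 1
                            continue
                        acc += (Tc[r] @ Yc[c]) / (tnorm * np.sqrt(cross))
                        cnt += 1
                if cnt == 0:
                    raise CTTError(
                        "cv_correlation undefined: no chunk pair with positive "
                        "cross-chunk signal variance (data may be pure noise)")
            else:
                for (r, rp) in run_pairs:
                    for (c, cp) in chunk_pairs:
                        d1 = T_stack[r, k] - means[i, c]
                        d2 = T_stack[rp, k] - means[i, cp]
                        acc += d1 @ d2
                        cnt += 1
            values[i, k] = acc / cnt

    return TrackingResult(
        indexes=values,
        metric=metric,
        condition_names=list(ts.condition_names),
        observation_conditions=np.asarray(conds),
        observation_runs=np.full(n_cells, -1),
        metadata={
            "tracker": "crossvalidated_index",
            "per": "condition_cell",
            "n_chunks": int(chunks.size),
            "cross_template_runs": bool(cross_template_runs),
            "n_negative": int((values < 0).sum()),
            "n_dropped_pairs": int(n_dropped),
        },
    )


def regression_partition(main: PatternSet, ts: TemplateSet,
                         standardize: bool = False,
                         max_condition_number: float = 1e8) -> TrackingResult:
    """Multiple regression of each pattern on all templates simultaneously.

    Pattern and templates are centered across units before the fit (no
    intercept), removing the global-mean component that reflects general
    rather than content-specific activation.  Returns per-template betas in
    ``indexes``, full-model R-squared in ``r_squared``, and signed
    semi-partial correlations (``sr_k = sign(beta_k) *
    sqrt(R2_full - R2_without_k)``) in ``semipartial_r`` — the unique
    variance contribution of each template.
    """
    _check_support(main, ts)
    K = ts.n_conditions
    X = _center_rows(ts.templates).T  # (V, K)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValidationError("cannot standardize a constant template")
        X = X / sd
    if K > 1:
        cond_number = np.linalg.cond(X)
        if cond_number > max_condition_number:
            raise ValidationError(
                f"templates are collinear (condition number {cond_number:.3g} "
                f"> {max_condition_number:.3g})")
    Y = _center_rows(main.patterns).T  # (V, n_obs)
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (K, n_obs)
    fitted = X @ betas
    ss_tot = (Y**2).sum(axis=0)
    if (ss_tot == 0).any():
        raise ValidationError("zero-variance observation pattern in regression")
    r2_full = 1.0 - ((Y - fitted) ** 2).sum(axis=0) / ss_tot

    sr = np.empty((Y.shape[1], K))
    for k in range(K):
        if K == 1:
            r2_drop = np.zeros_like(r2_full)
        else:
            Xk = np.delete(X, k, axis=1)
            bk, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
            r2_drop = 1.0 - ((Y - Xk @ bk) ** 2).sum(axis=0) / ss_tot
        gain = np.clip(r2_full - r2_drop, 0.0, None)
        sr[:, k] = np.sign(betas[k]) * np.sqrt(gain)

    return TrackingResult(
        indexes=betas.T,
        metric="regression_beta",
        condition_names=list(ts.condition_names),
        observation_conditions=main.condition_labels,
        observation_runs=main.run_ids,
        observation_time_bins=main.time_bins,
        semipartial_r=sr,
        r_squared=r2_full,
        metadata={"tracker": "regression_partition", "standardize": standardize},
    )


def classifier_tracking(ts: TemplateSet, main: PatternSet,
                        shrinkage: float = 0.1) -> TrackingResult:
    """Linear-discriminant tracking: signed hyperplane distances per template.

    A linear discriminant with shrinkage-regularized pooled within-class
    covariance is trained on the localizer exemplars.  For each main-task
    observation the result holds one signed decision value ``d`` per
    template: the distance to the one-vs-rest hyperplane of that condition,
    positive on the template's side; larger ``|d|`` means a more confident
    assignment.  Predicted labels (argmax of ``d``; ties broken by lowest
    condition index) and, when the main labels name template conditions,
    overall accuracy are reported in metadata.
    """
    _check_support(main, ts)
    if ts.exemplars is None:
        raise ValidationError("classifier tracking needs a TemplateSet with exemplars")
    K = ts.n_conditions
    if K < 2:
        raise ValidationError("classifier tracking needs at least 2 conditions")
    few = [c for c in ts.condition_names
           if c not in ts.exemplars or ts.exemplars[c].shape[0] < 2]
    if few:
        raise ValidationError(f"conditions with fewer than 2 exemplars: {few}")

    V = ts.n_units
    mus = np.vstack([ts.exemplars[c].mean(axis=0) for c in ts.condition_names])
    n_total = sum(ts.exemplars[c].shape[0] for c in ts.condition_names)
    Sw = np.zeros((V, V))
    for k, c in enumerate(ts.condition_names):
        X = ts.exemplars[c] - mus[k]
        Sw += X.T @ X
    Sw /= max(n_total - K, 1)
    gamma = float(shrinkage)
    if not 0.0 <= gamma <= 1.0:
        raise ValidationError("shrinkage must lie in [0, 1]")
    cov = (1.0 - gamma) * Sw + gamma * np.diag(np.diag(Sw))
    eigmin = np.linalg.eigvalsh(cov)[0]
    if eigmin <= 1e-12:
        raise ValidationError(
            "pooled covariance is singular; increase the shrinkage intensity "
            "(e.g. shrinkage=0.1) or provide more exemplars")

    d = np.empty((main.n_observations, K))
    for k in range(K):
        mu_k = mus[k]
        mu_rest = np.delete(mus, k, axis=0).mean(axis=0)
        w = np.linalg.solve(cov, mu_k - mu_rest)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError(
                f"degenerate discriminant for condition {ts.condition_names[k]!r} "
                "(identical class means)")
        mid = 0.5 * (mu_k + mu_rest)
        d[:, k] = (main.patterns - mid) @ w / norm

    predicted = np.asarray(ts.condition_names)[np.argmax(d, axis=1)]
    meta: dict[str, Any] = {"tracker": "classifier_tracking", "shrinkage": gamma,
                            "predicted_labels": predicted}
    labeled = np.isin(main.condition_labels, ts.condition_names)
    if labeled.any():
        acc = float(np.mean(predicted[labeled] == main.condition_labels[labeled]))
        meta["accuracy"] = acc
        meta["n_labeled"] = int(labeled.sum())
    return TrackingResult(
        indexes=d,
        metric="classifier_d",
        condition_names=list(ts.condition_names),
        observation_conditions=main.condition_labels,
        observation_runs=main.run_ids,
        observation_time_bins=main.time_bins,
        metadata=meta,
    )


def relative_activation(tr: TrackingResult, target: str, baseline: str
                        ) -> TrackingResult:
    """Target-minus-baseline relative index, oriented so positive = target wins.

    For higher-is-active metrics the relative index is
    ``index(target) - index(baseline)``; for distance metrics the sign is
    flipped (``index(baseline) - index(target)``).  Pearson correlations are
    Fisher-z transformed before the subtraction (variance stabilization);
    other metrics are differenced on their native scale.
    """
    target, baseline = str(target), str(baseline)
    if target == baseline:
        raise ValidationError("target and baseline conditions must differ")
    t = tr.column(target).astype(float)
    b = tr.column(baseline).astype(float)
    if tr.metric == "pearson":
        t = np.arctanh(np.clip(t, -1.0 + 1e-15, 1.0 - 1e-15))
        b = np.arctanh(np.clip(b, -1.0 + 1e-15, 1.0 - 1e-15))
    if tr.polarity == "higher_is_more_active":
        rel = t - b
    else:
        rel = b - t
    new_contrasts = tr.relative_contrasts + [(target, baseline)]
    if tr.relative_indexes is None:
        rel_matrix = rel[:, None]
    else:
        rel_matrix = np.column_stack([tr.relative_indexes, rel])
    return TrackingResult(
        indexes=tr.indexes,
        metric=tr.metric,
        condition_names=list(tr.condition_names),
        observation_conditions=tr.observation_conditions,
        observation_runs=tr.observation_runs,
        observation_time_bins=tr.observation_time_bins,
        relative_indexes=rel_matrix,
        relative_contrasts=new_contrasts,
        semipartial_r=tr.semipartial_r,
        r_squared=tr.r_squared,
        metadata=dict(tr.metadata),
    )
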