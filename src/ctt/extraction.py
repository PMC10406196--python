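"""Activity-pattern extraction: run-wise/trial-wise GLM, supertrials, noise
normalization, temporal smoothing and PCA dimensionality reduction.

All operations are pure: they never mutate their input objects and the
returned :class:`~ctt.patterns.PatternSet` carries a provenance record of
the operation and its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .patterns import CTTError, PatternSet, ValidationError

__all__ = [
    "GlmResult",
    "NoiseModel",
    "fit_run_glm",
    "make_supertrials",
    "noise_normalize",
    "smooth_temporal",
    "reduce_dimensions",
    "estimate_noise_model",
    "events_to_design",
]


@dataclass
class GlmResult:
    """Ordinary-least-squares fit of one run: betas, t values, residuals.

    ``dof = timepoints - rank(design)``.  One regressor per condition
    (run-wise mode) or per trial (trial-wise mode); which one is purely a
    matter of how the design matrix was built.
    """

    betas: np.ndarray          # (p, V)
    t_values: np.ndarray       # (p, V)
    residuals: np.ndarray      # (T, V)
    dof: int
    regressor_names: list[str] | None = None

    @property
    def residual_sd(self) -> np.ndarray:
        """Per-unit residual standard deviation (sqrt of SSR / dof)."""
        return np.sqrt((self.residuals**2).sum(axis=0) / self.dof)


@dataclass
class NoiseModel:
    """Shrinkage-regularized spatial noise covariance and its whitener.

    ``covariance`` is the shrunk estimate ``(1 - gamma) * S + gamma * diag(S)``
    with ``S`` the empirical residual covariance; ``whitener`` is its inverse
    symmetric square root, so ``whitener @ covariance @ whitener.T ~ I``.
    """

    covariance: np.ndarray
    shrinkage: float
    whitener: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.whitener).all():
            raise ValidationError("whitener contains non-finite values")


def fit_run_glm(data: np.ndarray, design: np.ndarray,
                regressor_names: list[str] | None = None) -> GlmResult:
    """Fit Y = X B + E by ordinary least squares, one run at a time.

    Returns beta weights, their t values (beta / SE, with SE from the
    residual variance and the diagonal of ``(X'X)^-1``) and the residuals
    needed for noise modeling.  The design must have full column rank and
    fewer columns than timepoints.
    """
    Y = np.asarray(data, dtype=float)
    X = np.asarray(design, dtype=float)
    if Y.ndim != 2 or X.ndim != 2:
        raise ValidationError("data and design must be 2-D matrices")
    if Y.shape[0] != X.shape[0]:
        raise ValidationError(
            f"data has {Y.shape[0]} timepoints but design has {X.shape[0]} rows")
    T, p = X.shape
    if T <= p:
        raise ValidationError(
            f"need more timepoints ({T}) than regressors ({p}) to estimate noise")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify a minimal set of columns linearly dependent on the others
        dependent = []
        for j in range(p):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                dependent.append(regressor_names[j] if regressor_names else j)
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"columns dependent on the others: {dependent}")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    dof = T - p
    sigma2 = (resid**2).sum(axis=0) / dof           # (V,)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, np.inf * np.sign(B))
    return GlmResult(betas=B, t_values=t, residuals=resid, dof=dof,
                     regressor_names=regressor_names)


def events_to_design(events, n_timepoints: int, dt: float = 1.0,
                     trial_wise: bool = False) -> tuple[np.ndarray, list[str]]:
    """Boxcar design matrix from a BIDS-style events table.

    ``events`` is a DataFrame with columns ``onset``, ``duration``,
    ``trial_type`` (times in the same unit as ``dt``).  One regressor per
    trial_type, or per trial when ``trial_wise``.  No hemodynamic
    convolution is applied.
    """
    import pandas as pd

    events = pd.DataFrame(events)
    for col in ("onset", "duration", "trial_type"):
        if col not in events.columns:
            raise ValidationError(f"events table is missing column {col!r}")
    if trial_wise:
        names = [f"{row.trial_type}_trial{i}" for i, row in enumerate(events.itertuples())]
        groups = [[i] for i in range(len(events))]
    else:
        names = sorted(events["trial_type"].astype(str).unique())
        groups = [list(np.flatnonzero(events["trial_type"].astype(str) == n))
                  for n in names]
    X = np.zeros((n_timepoints, len(names)))
    for j, rows in enumerate(groups):
        for i in rows:
            a = int(np.floor(events["onset"].iloc[i] / dt))
            b = int(np.ceil((events["onset"].iloc[i] + events["duration"].iloc[i]) / dt))
            X[max(a, 0):min(b, n_timepoints), j] = 1.0
    return X, names


def _cells(ps: PatternSet):
    """Iterate (condition, run) cells as row-index arrays over trials."""
    for cond in ps.conditions:
        for run in np.unique(ps.run_ids):
            idx = np.flatnonzero((ps.condition_labels == cond) & (ps.run_ids == run))
            if idx.size:
                yield cond, run, idx


def make_supertrials(ps: PatternSet, group_size: int,
                     seed: int | None = 0) -> PatternSet:
    """Average random groups of ``group_size`` trials within condition x run.

    Trials are partitioned at random (seeded) inside each cell; groups
    smaller than ``group_size`` left over after the partition are discarded.
    For epoch data the grouping is over trials and the average is taken
    bin-by-bin, so the output keeps the time axis.
    """
    k = int(group_size)
    if k < 1:
        raise ValidationError("group_size must be >= 1")
    if k == 1:  # averaging singletons: identity on the data
        return ps.with_patterns(ps.patterns.copy(),
                                op={"op": "make_supertrials", "k": 1, "seed": seed})
    rng = np.random.default_rng(seed)
    epoch = ps.is_time_resolved
    if epoch and ps.trial_ids is None:
        raise ValidationError("epoch supertrials require trial_ids")

    too_small: list[tuple[str, object]] = []
    rows, conds, runs, bins, trials = [], [], [], [], []
    new_trial = 0
    for cond, run, idx in _cells(ps):
        if epoch:
            cell_trials = np.unique(ps.trial_ids[idx])
        else:
            cell_trials = idx
        if cell_trials.size < k:
            too_small.append((cond, run))
            continue
        perm = rng.permutation(cell_trials)
        n_groups = cell_trials.size // k
        for g in range(n_groups):
            members = perm[g * k:(g + 1) * k]
            if epoch:
                member_rows = np.flatnonzero(np.isin(ps.trial_ids, members))
                sub_bins = ps.time_bins[member_rows]
                for b in np.unique(sub_bins):
                    rows.append(ps.patterns[member_rows[sub_bins == b]].mean(axis=0))
                    conds.append(cond); runs.append(run)
                    bins.append(b); trials.append(new_trial)
            else:
                rows.append(ps.patterns[members].mean(axis=0))
                conds.append(cond); runs.append(run); trials.append(new_trial)
            new_trial += 1
    if too_small:
        raise ValidationError(
            f"condition x run cells with fewer than {k} trials: {too_small}")
    return PatternSet(
        patterns=np.vstack(rows),
        condition_labels=np.array(conds),
        run_ids=np.array(runs),
        time_bins=np.array(bins) if epoch else None,
        trial_ids=np.array(trials),
        unit_ids=ps.unit_ids,
        space=ps.space,
        geometry=ps.geometry,
        provenance=ps.provenance + [{"op": "make_supertrials", "k": k, "seed": seed}],
    )


# -- noise normalization -----------------------------------------------------

def _optimal_shrinkage(residuals: np.ndarray) -> float:
    """Analytic optimal shrinkage intensity toward the diagonal target.

    Ledoit-Wolf-style estimator (Schafer & Strimmer 2005): gamma* =
    sum of estimated variances of the off-diagonal covariance entries over
    the sum of their squares, clipped to [0, 1].
    """
    X = residuals - residuals.mean(axis=0, keepdims=True)
    n = X.shape[0]
    S = (X.T @ X) / (n - 1)
    X2 = X**2
    var_S = (X2.T @ X2) / (n - 1) - S**2 * (n - 2) / (n - 1)
    var_S = var_S * n / ((n - 1) ** 2)
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = (S[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_S[off].sum() / denom, 0.0, 1.0))


def estimate_noise_model(residuals: np.ndarray, dof: int | None = None,
                         shrinkage: float | None = None,
                         min_timepoints: int = 10) -> NoiseModel:
    """Shrinkage covariance of GLM residuals and its inverse square root.

    ``dof`` defaults to ``n_timepoints - 1``; with ``shrinkage=None`` the
    analytic optimal intensity is used.  ``shrinkage=1`` reduces the model
    to the diagonal, making multivariate whitening identical to univariate
    scaling by the per-unit residual SD.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2:
        raise ValidationError("residuals must be a timepoints x units matrix")
    if R.shape[0] < min_timepoints:
        raise ValidationError(
            f"need at least {min_timepoints} residual timepoints, got {R.shape[0]}")
    if dof is None:
        dof = R.shape[0] - 1
    S = (R.T @ R) / dof
    gamma = _optimal_shrinkage(R) if shrinkage is None else float(shrinkage)
    if not 0.0 <= gamma <= 1.0:
        raise ValidationError("shrinkage must lie in [0, 1]")
    target = np.diag(np.diag(S))
    cov = (1.0 - gamma) * S + gamma * target
    diag = np.diag(cov)
    if np.array_equal(cov, np.diag(diag)):
        # exactly diagonal (gamma = 1, or uncorrelated residuals): the
        # whitener reduces to per-unit scaling, computed exactly
        if diag.min() <= 0:
            raise ValidationError(
                "residual covariance is not positive definite after shrinkage "
                f"(zero variance units present)")
        whitener = np.diag(1.0 / np.sqrt(diag))
    else:
        eigval, eigvec = np.linalg.eigh(cov)
        if eigval.min() <= 0:
            raise ValidationError(
                "residual covariance is not positive definite after shrinkage "
                f"(min eigenvalue {eigval.min():.3e}); increase shrinkage")
        whitener = (eigvec * (1.0 / np.sqrt(eigval))) @ eigvec.T
    return NoiseModel(covariance=cov, shrinkage=gamma, whitener=whitener)


def noise_normalize(ps: PatternSet, mode: str,
                    glm: GlmResult | None = None,
                    noise: NoiseModel | None = None,
                    residual_sd: np.ndarray | None = None) -> PatternSet:
    """Univariate (t-value) or multivariate (whitening) noise normalization.

    ``univariate`` divides every unit by its residual SD — on GLM betas this
    is exactly the replacement of betas by t values up to the common design
    factor.  ``multivariate`` right-multiplies the patterns by the whitener
    of a shrinkage-regularized residual covariance.
    """
    if mode == "univariate":
        if residual_sd is None:
            if glm is None:
                raise ValidationError(
                    "univariate normalization needs residual_sd or a GlmResult")
            residual_sd = glm.residual_sd
        sd = np.asarray(residual_sd, dtype=float)
        if sd.shape != (ps.n_units,):
            raise ValidationError("residual_sd length must equal unit count")
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValidationError(
                f"zero residual SD at units {ps.unit_ids[zero][:10].tolist()}")
        out = ps.patterns * (1.0 / sd)
    elif mode == "multivariate":
        if noise is None:
            if glm is None:
                raise ValidationError(
                    "multivariate normalization needs a NoiseModel or a GlmResult")
            noise = estimate_noise_model(glm.residuals, dof=glm.dof)
        if noise.whitener.shape != (ps.n_units, ps.n_units):
            raise ValidationError("NoiseModel dimension must equal unit count")
        W = noise.whitener
        if np.array_equal(W, np.diag(np.diag(W))):
            out = ps.patterns * np.diag(W)  # identical arithmetic to univariate
        else:
            out = ps.patterns @ W
    else:
        raise ValidationError("mode must be 'univariate' or 'multivariate'")
    return ps.with_patterns(out, op={"op": "noise_normalize", "mode": mode})


def smooth_temporal(ps: PatternSet, window: int) -> PatternSet:
    """Centered moving average over time bins within each trial.

    ``window`` must be odd; bins near the epoch edges use truncated windows
    (the average runs over the in-range bins only — no padding).
    """
    w = int(window)
    if w < 1 or w % 2 == 0:
        raise ValidationError("window must be an odd integer >= 1")
    if not ps.is_time_resolved or ps.trial_ids is None:
        raise ValidationError("temporal smoothing requires epoch data with trial_ids")
    half = w // 2
    out = ps.patterns.copy()
    for trial in np.unique(ps.trial_ids):
        rows = np.flatnonzero(ps.trial_ids == trial)
        order = np.argsort(ps.time_bins[rows])
        rows = rows[order]
        n = rows.size
        if w > n:
            raise ValidationError(
                f"window {w} exceeds the {n} time bins of trial {trial}")
        vals = ps.patterns[rows]
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            out[rows[i]] = vals[lo:hi].mean(axis=0)
    return ps.with_patterns(out, op={"op": "smooth_temporal", "window": w})


def reduce_dimensions(train: PatternSet, apply_to: list[PatternSet],
                      variance_fraction: float = 0.99
                      ) -> tuple[list[PatternSet], PCA]:
    """PCA fitted on the training set only; projection applied everywhere.

    Retains the minimal number of components whose cumulative explained
    variance ratio reaches ``variance_fraction``.  Fitting on localizer data
    only (the recommended usage) keeps main-task information out of the
    projection and avoids train/test leakage.
    """
    f = float(variance_fraction)
    if not 0.0 < f <= 1.0:
        raise ValidationError("variance_fraction must lie in (0, 1]")
    if train.n_observations < 2:
        raise ValidationError("PCA needs at least 2 training observations")
    for other in apply_to:
        if not train.same_support(other):
            raise ValidationError("apply_to PatternSets must share the training unit support")
    pca = PCA()
    pca.fit(train.patterns)
    ratios = pca.explained_variance_ratio_
    nonzero = int((pca.explained_variance_ > 1e-12).sum())
    cum = np.cumsum(ratios)
    d = int(np.searchsorted(cum, f - 1e-12) + 1)
    d = min(max(d, 1), nonzero if nonzero else 1)
    pca.components_ = pca.components_[:d]
    pca.explained_variance_ = pca.explained_variance_[:d]
    pca.explained_variance_ratio_ = ratios[:d]
    pca.n_components_ = d

    def project(ps: PatternSet) -> PatternSet:
        comp = pca.transform(ps.patterns)
        new = ps.with_patterns(
            comp,
            op={"op": "reduce_dimensions", "variance_fraction": f, "n_components": d},
            unit_ids=np.arange(d),
            space="component",
            geometry=None,
        )
        return new

    return [project(ps) for ps in apply_to], pca
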