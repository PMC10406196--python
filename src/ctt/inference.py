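"""Group-level statistics for activation indexes.

Tracking measurements rarely satisfy parametric assumptions, so inference
is non-parametric throughout: Wilcoxon signed-rank tests, permutation nulls
(trial-label shuffling at the subject level, sign flipping of per-subject
relative indexes at the group level), cluster-based family-wise-error
correction over contiguous voxels or time bins, and Benjamini-Hochberg FDR.

The recommended pipeline for relative activation indexes is: per-subject
relative index map -> group sign-flip permutation -> cluster-size FWE
correction, one-sided (the directional hypothesis "target more active than
baseline").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .mapping import StatMap
from .patterns import ValidationError

__all__ = [
    "WilcoxonResult",
    "GroupInferenceResult",
    "wilcoxon_signed_rank",
    "permutation_test",
    "cluster_correct",
    "fdr_correct",
]

_EXACT_WILCOXON_MAX_N = 25
_ENUMERATION_MAX_N = 12  # full 2^n sign enumeration below this group size


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    n_zeros_dropped: int
    alternative: str
    method: str  # "exact" | "approx"


@dataclass
class GroupInferenceResult:
    """Statistics, p values and (optionally) cluster table for one analysis."""

    statistic: np.ndarray
    p_values: np.ndarray
    null_distribution: np.ndarray | None = None
    cluster_table: pd.DataFrame | None = None
    correction: str = "none"
    n_permutations: int = 0
    seed: int | None = None
    exhaustive: bool = False
    alternative: str = "greater"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.statistic = np.atleast_1d(np.asarray(self.statistic, dtype=float))
        self.p_values = np.atleast_1d(np.asarray(self.p_values, dtype=float))
        finite = self.p_values[np.isfinite(self.p_values)]
        if finite.size and ((finite <= 0).any() or (finite > 1).any()):
            raise ValidationError("p values must lie in (0, 1]")

    def null_summary(self) -> dict[str, float]:
        if self.null_distribution is None:
            return {}
        null = self.null_distribution
        return {
            "null_mean": float(np.nanmean(null)),
            "null_sd": float(np.nanstd(null)),
            "null_q95": float(np.nanquantile(null, 0.95)),
        }


def wilcoxon_signed_rank(values: Sequence[float], mu: float = 0.0,
                         paired_with: Sequence[float] | None = None,
                         alternative: str = "greater") -> WilcoxonResult:
    """Wilcoxon signed-rank test of ``values`` against ``mu`` or a paired sample.

    Zero differences are dropped (classic Wilcoxon convention) and their
    count reported.  The null distribution is exact (sign enumeration) for
    n <= 25 without ties, and a normal approximation with continuity
    correction above.  The one-sample form should only be used on indexes
    whose positive noise bias is controlled (cross-validated estimators);
    biased naive indexes call for the paired form against a baseline
    template.
    """
    x = np.asarray(values, dtype=float)
    if paired_with is not None:
        y = np.asarray(paired_with, dtype=float)
        if y.shape != x.shape:
            raise ValidationError("paired samples must have equal length")
        d = x - y
    else:
        d = x - mu
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("all differences are zero; the test is undefined")
    if d.size < 5:
        raise ValidationError(
            f"need at least 5 nonzero differences, got {d.size}")
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= _EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n_used=int(d.size), n_zeros_dropped=n_zero,
                          alternative=alternative, method=method)


def _all_sign_patterns(n: int) -> np.ndarray:
    """(2^n, n) array of +-1 sign patterns, identity first."""
    signs = np.array(list(product((1.0, -1.0), repeat=n)))
    return signs


def _compare(null: np.ndarray, obs: np.ndarray, alternative: str) -> np.ndarray:
    tol = 1e-10 * (1.0 + np.abs(obs))
    if alternative == "greater":
        return null >= obs - tol
    if alternative == "less":
        return null <= obs + tol
    return np.abs(null) >= np.abs(obs) - tol


def permutation_test(data: np.ndarray, scheme: str, n_perm: int = 1000,
                     seed: int = 0, statistic: str = "mean",
                     labels: np.ndarray | None = None,
                     target: str | None = None, baseline: str | None = None,
                     alternative: str = "greater") -> GroupInferenceResult:
    """Permutation null for activation indexes.

    ``scheme="group_sign_flip"``: ``data`` is subjects x units of relative
    indexes; the null flips each subject's sign (exchangeable under the
    no-effect null because the relative index is sign-symmetric).  With
    n <= 12 subjects the full 2^n enumeration replaces random sampling and
    the test is exact and reproducible without an RNG.

    ``scheme="trial_label_shuffle"``: ``data`` is trials x units with
    ``labels`` naming each trial's condition; the statistic is the
    target-minus-baseline difference of label means and the null shuffles
    the labels.

    p values use the add-one rule ``(1 + #{null >= obs}) / (1 + n_perm)``
    (exhaustive enumeration divides by the enumeration count instead, the
    identity permutation being part of the null).  The full null sample is
    retained for downstream cluster correction.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    if statistic not in ("mean", "t"):
        raise ValidationError("statistic must be 'mean' or 't'")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")

    if scheme == "group_sign_flip":
        n = data.shape[0]
        if n < 2:
            raise ValidationError("group sign-flip needs at least 2 subjects")

        def stat_of(means: np.ndarray) -> np.ndarray:
            # means: (n_draws, U) of per-draw subject means
            if statistic == "mean":
                return means
            # sign flips leave per-subject squares unchanged: the second
            # moment is constant across flips, so sd depends only on the mean
            msq = (data**2).mean(axis=0)  # (U,)
            var = (msq - means**2) * n / (n - 1)
            var = np.clip(var, 1e-300, None)
            return means / np.sqrt(var / n)

        obs = stat_of(data.mean(axis=0)[None, :])[0]
        exhaustive = n <= _ENUMERATION_MAX_N
        if exhaustive:
            signs = _all_sign_patterns(n)
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice([1.0, -1.0], size=(n_perm, n))
        null_means = (signs @ data) / n
        nulls = stat_of(null_means)
        hits = _compare(nulls, obs[None, :], alternative).sum(axis=0)
        if exhaustive:
            p = hits / nulls.shape[0]
            p = np.clip(p, 1.0 / nulls.shape[0], 1.0)
        else:
            p = (1.0 + hits) / (1.0 + n_perm)
        return GroupInferenceResult(
            statistic=obs, p_values=p, null_distribution=nulls,
            correction="none", n_permutations=int(nulls.shape[0]),
            seed=None if exhaustive else seed, exhaustive=exhaustive,
            alternative=alternative,
            metadata={"scheme": scheme, "statistic": statistic})

    if scheme == "trial_label_shuffle":
        if labels is None or target is None or baseline is None:
            raise ValidationError(
                "trial_label_shuffle needs labels, target and baseline")
        labels = np.asarray(labels).astype(str)
        if labels.shape[0] != data.shape[0]:
            raise ValidationError("labels length must equal trial count")
        t_idx = labels == str(target)
        b_idx = labels == str(baseline)
        if not t_idx.any() or not b_idx.any():
            raise ValidationError("target/baseline labels missing from trials")

        def diff(lab: np.ndarray) -> np.ndarray:
            return data[lab == str(target)].mean(axis=0) \
                - data[lab == str(baseline)].mean(axis=0)

        obs = diff(labels)
        rng = np.random.default_rng(seed)
        nulls = np.empty((n_perm, data.shape[1]))
        for i in range(n_perm):
            nulls[i] = diff(rng.permutation(labels))
        hits = _compare(nulls, obs[None, :], alternative).sum(axis=0)
        p = (1.0 + hits) / (1.0 + n_perm)
        return GroupInferenceResult(
            statistic=obs, p_values=p, null_distribution=nulls,
            correction="none", n_permutations=n_perm, seed=seed,
            exhaustive=False, alternative=alternative,
            metadata={"scheme": scheme, "statistic": statistic,
                      "target": str(target), "baseline": str(baseline)})

    raise ValidationError(f"unknown permutation scheme {scheme!r}")


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim == 1:
        return np.ones(3, dtype=bool)
    if ndim == 3:
        if connectivity == 6:
            return ndimage.generate_binary_structure(3, 1)
        if connectivity == 18:
            return ndimage.generate_binary_structure(3, 2)
        if connectivity == 26:
            return ndimage.generate_binary_structure(3, 3)
        raise ValidationError("3-D connectivity must be 6, 18 or 26")
    if ndim == 2:
        return ndimage.generate_binary_structure(2, 1)
    raise ValidationError(f"unsupported map dimensionality {ndim}")


def _cluster_stats(stat: np.ndarray, thresh: np.ndarray, structure: np.ndarray,
                   cluster_stat: str) -> tuple[np.ndarray, list[dict]]:
    thresh = np.broadcast_to(np.asarray(thresh, dtype=float), stat.shape)
    finite = np.isfinite(stat)
    supra = np.zeros(stat.shape, dtype=bool)
    supra[finite] = stat[finite] > thresh[finite]
    labeled, n = ndimage.label(supra, structure=structure)
    clusters = []
    for cid in range(1, n + 1):
        members = labeled == cid
        size = int(members.sum())
        mass = float((stat[members] - thresh[members]).sum())
        clusters.append({"id": cid, "size": size, "mass": mass,
                         "stat": size if cluster_stat == "size" else mass,
                         "members": np.flatnonzero(members.ravel()).tolist()})
    return labeled, clusters


def cluster_correct(stat_map: "StatMap | np.ndarray",
                    null_maps: np.ndarray,
                    forming_threshold: "float | tuple[str, float]" = ("p", 0.05),
                    connectivity: int = 6,
                    cluster_stat: str = "size",
                    exhaustive: bool = False) -> GroupInferenceResult:
    """Cluster-level FWE correction from a permutation null.

    The observed and every null map are thresholded (a fixed statistic
    cutoff, or ``("p", alpha)`` for the per-unit ``1 - alpha`` quantile of
    the null), contiguous suprathreshold units are labeled (1-D adjacency
    for time courses, 6/18/26-connectivity for volumes) and the maximal
    cluster statistic of each null map forms the null distribution; each
    observed cluster's FWE p compares its statistic against that null.

    ``cluster_stat="size"`` uses the member count (the classic cluster-size
    criterion); ``"mass"`` uses the summed threshold exceedance, whose
    continuous null distribution avoids the heavy discreteness of small
    integer sizes.
    """
    values = stat_map.values if isinstance(stat_map, StatMap) else np.asarray(stat_map)
    null_maps = np.asarray(null_maps, dtype=float)
    if null_maps.shape[1:] != values.shape:
        raise ValidationError(
            f"null maps shape {null_maps.shape[1:]} does not match the "
            f"observed map shape {values.shape}")
    if cluster_stat not in ("size", "mass"):
        raise ValidationError("cluster_stat must be 'size' or 'mass'")
    n_null = null_maps.shape[0]
    if isinstance(forming_threshold, tuple):
        kind, alpha = forming_threshold
        if kind != "p" or not 0 < alpha < 1:
            raise ValidationError("forming_threshold must be a float or ('p', alpha)")
        thresh = np.quantile(null_maps, 1.0 - alpha, axis=0)
    else:
        thresh = np.full(values.shape, float(forming_threshold))

    structure = _structure(values.ndim, connectivity)
    labeled, clusters = _cluster_stats(values, thresh, structure, cluster_stat)
    null_max = np.empty(n_null)
    for i in range(n_null):
        _, nc = _cluster_stats(null_maps[i], thresh, structure, cluster_stat)
        null_max[i] = max((c["stat"] for c in nc), default=0.0)

    rows = []
    for c in clusters:
        hits = int((null_max >= c["stat"] - 1e-12).sum())
        if exhaustive:
            p = max(hits, 1) / n_null
        else:
            p = (1.0 + hits) / (1.0 + n_null)
        rows.append({"cluster_id": c["id"], "size": c["size"],
                     "mass": c["mass"], "p_fwe": p, "members": c["members"]})
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "mass",
                                        "p_fwe", "members"])
    p_map = np.full(values.shape, np.nan)
    for row in rows:
        p_map.ravel()[row["members"]] = row["p_fwe"]
    return GroupInferenceResult(
        statistic=values.ravel(), p_values=np.where(np.isfinite(p_map.ravel()),
                                                    p_map.ravel(), 1.0),
        null_distribution=null_max[:, None],
        cluster_table=table, correction="cluster_fwe",
        n_permutations=n_null, exhaustive=exhaustive,
        metadata={"connectivity": connectivity, "cluster_stat": cluster_stat,
                  "labeled_map": labeled, "forming_threshold": forming_threshold})


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p value array")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
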