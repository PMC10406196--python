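"""Drive template tracking over space (searchlight) and time (per-bin,
temporal generalization).

The searchlight iterates a sphere of fixed voxel radius over every in-mask
voxel, re-estimates the canonical templates from the localizer voxels
inside the sphere, tracks them on the main-task data restricted to the same
voxels, reduces the result to one scalar, and assigns it to the center
voxel.  The temporal driver does the analogous thing over time bins, with
optional generalization: templates from localizer bin ``t`` tracked on
main-task bin ``t'`` for every pair ``(t, t')``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Any

import numpy as np

from .patterns import PatternSet, ValidationError

__all__ = [
    "SearchlightSpec",
    "TrackerConfig",
    "StatMap",
    "TemporalGeneralizationMatrix",
    "sphere_offsets",
    "run_searchlight",
    "run_temporal",
]

MISSING = np.nan

_CORRELATION_METRICS = ("pearson", "fisher_z")


@dataclass
class TrackerConfig:
    """How a mapped analysis turns one sphere/bin into a scalar.

    ``scalar="relative"`` computes, per main observation, the
    target-minus-baseline relative index (Fisher z for correlations,
    polarity-flipped for distances) and reduces across observations with
    ``reducer``.  ``scalar="matched"`` correlates each condition's localizer
    mean with the same condition's main-task mean and averages across
    conditions — a symmetric summary useful for temporal generalization.
    """

    metric: str = "pearson"
    target: str | None = None
    baseline: str | None = None
    scalar: str = "relative"
    reducer: str = "mean"
    main_condition: str | None = None  # restrict main observations; None = all

    def __post_init__(self) -> None:
        if self.metric not in ("pearson", "fisher_z", "euclidean", "sq_euclidean"):
            raise ValidationError(f"unsupported mapping metric {self.metric!r}")
        if self.scalar not in ("relative", "matched"):
            raise ValidationError("scalar must be 'relative' or 'matched'")
        if self.reducer not in ("mean", "median"):
            raise ValidationError("reducer must be 'mean' or 'median'")
        if self.scalar == "relative" and (self.target is None or self.baseline is None):
            raise ValidationError("scalar='relative' needs target and baseline conditions")


@dataclass
class SearchlightSpec:
    """Sphere radius (voxels), brain mask and minimum in-mask sphere size."""

    radius: float
    mask: np.ndarray
    min_voxels: int = 12

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValidationError("radius must be >= 0")
        if self.min_voxels < 1:
            raise ValidationError("min_voxels must be >= 1")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValidationError("mask must be a 3-D volume")


@dataclass
class StatMap:
    """Per-voxel (3-D) or per-time-bin (1-D) statistic array.

    Out-of-mask / skipped entries carry NaN.  ``geometry`` is the source
    :class:`~ctt.patterns.VolumeGeometry` for volumes, or the array of bin
    indexes for time maps.
    """

    values: np.ndarray
    kind: str  # "volume" | "time"
    statistic: str
    geometry: Any = None
    bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("volume", "time"):
            raise ValidationError("kind must be 'volume' or 'time'")
        if self.kind == "volume" and self.values.ndim != 3:
            raise ValidationError("volume StatMap values must be 3-D")
        if self.kind == "time":
            if self.values.ndim != 1:
                raise ValidationError("time StatMap values must be 1-D")
            if self.bins is None or len(self.bins) != self.values.size:
                raise ValidationError("time StatMap needs one bin label per value")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class TemporalGeneralizationMatrix:
    """T_localizer x T_main matrix of tracking scalars."""

    values: np.ndarray
    localizer_bins: np.ndarray
    main_bins: np.ndarray
    statistic: str = "relative_index"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.localizer_bins), len(self.main_bins)):
            raise ValidationError("matrix shape must be (n_localizer_bins, n_main_bins)")

    def diagonal(self) -> tuple[np.ndarray, np.ndarray]:
        """Shared-bin diagonal: (bins, values) where both axes sample the bin."""
        shared = [b for b in self.localizer_bins if b in set(self.main_bins)]
        li = {b: i for i, b in enumerate(self.localizer_bins)}
        mi = {b: j for j, b in enumerate(self.main_bins)}
        vals = np.array([self.values[li[b], mi[b]] for b in shared])
        return np.asarray(shared), vals


def sphere_offsets(radius: float) -> list[tuple[int, int, int]]:
    """Integer offsets (dx, dy, dz) with dx^2+dy^2+dz^2 <= radius^2.

    Deterministic lexicographic order.  radius 0 -> the center only;
    radius 1 -> center plus the 6 face neighbors.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    r = int(np.floor(radius))
    r2 = radius * radius
    return [
        (dx, dy, dz)
        for dx, dy, dz in product(range(-r, r + 1), repeat=3)
        if dx * dx + dy * dy + dz * dz <= r2
    ]


# -- scalar tracking kernel ---------------------------------------------------

def _condition_means(Y: np.ndarray, labels: np.ndarray,
                     conds: list[str]) -> np.ndarray:
    out = np.empty((len(conds), Y.shape[1]))
    for k, c in enumerate(conds):
        idx = labels == c
        if not idx.any():
            raise ValidationError(f"condition {c!r} has no observations")
        out[k] = Y[idx].mean(axis=0)
    return out


def _pairwise_index(Y: np.ndarray, T: np.ndarray, metric: str) -> np.ndarray:
    """(n_obs x K) index matrix between pattern rows and template rows."""
    if metric in _CORRELATION_METRICS:
        Yc = Y - Y.mean(axis=1, keepdims=True)
        Tc = T - T.mean(axis=1, keepdims=True)
        yn = np.linalg.norm(Yc, axis=1)
        tn = np.linalg.norm(Tc, axis=1)
        if (yn == 0).any() or (tn == 0).any():
            return np.full((Y.shape[0], T.shape[0]), np.nan)
        r = np.clip((Yc @ Tc.T) / np.outer(yn, tn), -1.0, 1.0)
        if metric == "fisher_z":
            r = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        return r
    d2 = ((Y[:, None, :] - T[None, :, :]) ** 2).sum(axis=-1)
    return d2 if metric == "sq_euclidean" else np.sqrt(d2)


def _track_scalar(loc_Y: np.ndarray, loc_labels: np.ndarray,
                  main_Y: np.ndarray, main_labels: np.ndarray,
                  conds: list[str], cfg: TrackerConfig) -> float:
    """One tracking scalar from localizer and main data on a shared support."""
    T = _condition_means(loc_Y, loc_labels, conds)
    if cfg.scalar == "matched":
        shared = [c for c in conds if (main_labels == c).any()]
        if not shared:
            return np.nan
        M = _condition_means(main_Y, main_labels, shared)
        Tm = T[[conds.index(c) for c in shared]]
        vals = np.array([
            _pairwise_index(M[i:i + 1], Tm[i:i + 1], cfg.metric)[0, 0]
            for i in range(len(shared))
        ])
        return float(np.nanmean(vals))
    # relative: per-observation target-minus-baseline index
    try:
        kt = conds.index(cfg.target)
        kb = conds.index(cfg.baseline)
    except ValueError:
        raise ValidationError(
            f"target/baseline {cfg.target!r}/{cfg.baseline!r} not among the "
            f"localizer conditions {conds}") from None
    if cfg.main_condition is not None:
        keep = main_labels == cfg.main_condition
        if not keep.any():
            return np.nan
        main_Y = main_Y[keep]
    idx = _pairwise_index(main_Y, T[[kt, kb]], cfg.metric)
    if np.isnan(idx).all():
        return np.nan
    t, b = idx[:, 0], idx[:, 1]
    if cfg.metric == "pearson":
        t = np.arctanh(np.clip(t, -1 + 1e-15, 1 - 1e-15))
        b = np.arctanh(np.clip(b, -1 + 1e-15, 1 - 1e-15))
    rel = (t - b) if cfg.metric in _CORRELATION_METRICS else (b - t)
    reduce = np.nanmean if cfg.reducer == "mean" else np.nanmedian
    return float(reduce(rel))


# -- searchlight --------------------------------------------------------------

def run_searchlight(loc: PatternSet, main: PatternSet, spec: SearchlightSpec,
                    tracker: TrackerConfig | None = None) -> StatMap:
    """Sphere-by-sphere template tracking over a volume.

    For every in-mask voxel, both datasets are restricted to the in-mask
    voxels of the sphere centered there; templates are estimated from the
    localizer, tracked on the main data, and reduced to one scalar that is
    assigned to the center.  Spheres with fewer than ``min_voxels`` in-mask
    voxels (mask edges, corners) are skipped and carry NaN.
    """
    tracker = tracker or TrackerConfig()
    if loc.space != "volume" or main.space != "volume":
        raise ValidationError("searchlight requires volumetric PatternSets")
    if loc.geometry is None or main.geometry is None \
            or not loc.geometry.matches(main.geometry):
        raise ValidationError("localizer and main volumes have mismatched geometry")
    shape = loc.geometry.shape
    if spec.mask.shape != shape:
        raise ValidationError(
            f"mask shape {spec.mask.shape} does not match volume shape {shape}")
    if spec.radius == 0 and tracker.metric in _CORRELATION_METRICS:
        raise ValidationError(
            "radius-0 spheres hold a single voxel; correlation metrics are "
            "undefined on one unit — use a distance metric or radius >= 1")
    if not np.array_equal(loc.unit_ids, main.unit_ids):
        raise ValidationError("localizer and main must share voxel support")

    # 3-D lookup: voxel -> column in the pattern matrices (-1 when absent)
    col_of = np.full(shape, -1, dtype=np.int64)
    coords = np.column_stack(np.unravel_index(
        np.asarray(loc.unit_ids, dtype=np.int64), shape, order="C"))
    col_of[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(loc.n_units)
    usable = spec.mask & (col_of >= 0)
    centers = np.argwhere(usable)
    if centers.size == 0:
        raise ValidationError("no valid searchlight centers (empty mask overlap)")

    offsets = np.asarray(sphere_offsets(spec.radius), dtype=np.int64)
    conds = loc.conditions
    loc_Y, loc_lab = loc.patterns, loc.condition_labels
    main_Y, main_lab = main.patterns, main.condition_labels

    values = np.full(shape, MISSING)
    for cx, cy, cz in centers:
        pts = offsets + np.array([cx, cy, cz])
        ok = ((pts >= 0) & (pts < np.asarray(shape))).all(axis=1)
        pts = pts[ok]
        inmask = usable[pts[:, 0], pts[:, 1], pts[:, 2]]
        cols = col_of[pts[inmask, 0], pts[inmask, 1], pts[inmask, 2]]
        if cols.size < spec.min_voxels:
            continue
        values[cx, cy, cz] = _track_scalar(
            loc_Y[:, cols], loc_lab, main_Y[:, cols], main_lab, conds, tracker)
    return StatMap(values=values, kind="volume",
                   statistic=f"{tracker.scalar}_{tracker.metric}",
                   geometry=loc.geometry)


# -- temporal -----------------------------------------------------------------

def run_temporal(loc: PatternSet, main: PatternSet, generalize: bool = False,
                 tracker: TrackerConfig | None = None
                 ) -> "StatMap | TemporalGeneralizationMatrix":
    """Per-time-bin tracking, optionally generalized across bin pairs.

    ``generalize=False``: templates and main patterns come from the same
    bin; returns a time-course :class:`StatMap` over the bins both datasets
    sample.  ``generalize=True``: templates from localizer bin ``t`` are
    tracked on main patterns from bin ``t'`` for every pair, returning the
    full :class:`TemporalGeneralizationMatrix` whose diagonal (where the
    axes share bins) equals the time-resolved output exactly.
    """
    tracker = tracker or TrackerConfig()
    if not loc.is_time_resolved or not main.is_time_resolved:
        raise ValidationError("temporal mapping requires epoch data on both sides")
    if not loc.same_support(main):
        raise ValidationError("localizer and main must share channel support")
    loc_bins = np.unique(loc.time_bins)
    main_bins = np.unique(main.time_bins)
    conds = loc.conditions

    def cell(t: int, tp: int) -> float:
        li = loc.time_bins == t
        mi = main.time_bins == tp
        return _track_scalar(loc.patterns[li], loc.condition_labels[li],
                             main.patterns[mi], main.condition_labels[mi],
                             conds, tracker)

    if generalize:
        values = np.empty((loc_bins.size, main_bins.size))
        for i, t in enumerate(loc_bins):
            for j, tp in enumerate(main_bins):
                values[i, j] = cell(t, tp)
        return TemporalGeneralizationMatrix(
            values=values, localizer_bins=loc_bins, main_bins=main_bins,
            statistic=f"{tracker.scalar}_{tracker.metric}")

    shared = np.intersect1d(loc_bins, main_bins)
    if shared.size == 0:
        raise ValidationError("no time bins shared between localizer and main data")
    values = np.array([cell(t, t) for t in shared])
    return StatMap(values=values, kind="time",
                   statistic=f"{tracker.scalar}_{tracker.metric}", bins=shared)
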