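"""Labeled activity-pattern containers shared by every analysis stage.

A :class:`PatternSet` is the package's central in-memory object: an
``observations x units`` matrix of activity values (beta weights, t values,
voltages, ...) together with per-observation condition / run / time-bin
labels and per-unit identifiers.  A :class:`TemplateSet` holds one canonical
pattern per localizer condition, optionally with the trial exemplars and
run-wise estimates that classifier-based and cross-validated tracking need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

__all__ = [
    "CTTError",
    "ValidationError",
    "VolumeGeometry",
    "PatternSet",
    "TemplateSet",
]


class CTTError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(CTTError, ValueError):
    """An input object violated a documented precondition."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape and affine of the source NIfTI volume a PatternSet came from."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValidationError("affine must be a 4x4 matrix")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def matches(self, other: "VolumeGeometry", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


def _as_1d(name: str, values: Sequence, n: int | None = None) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if n is not None and arr.shape[0] != n:
        raise ValidationError(
            f"{name} has length {arr.shape[0]}, expected {n} (one per observation)"
        )
    return arr


@dataclass
class PatternSet:
    """Observations x units activity matrix with aligned labels.

    Parameters
    ----------
    patterns
        ``(n_obs, V)`` float array; must be finite.
    condition_labels
        Condition name per observation.
    run_ids
        Run (localizer) or chunk (main task) id per observation.
    time_bins
        Optional time-bin index per observation (epoch data).
    trial_ids
        Optional trial id per observation; required by operations that act
        within a trial across time bins (smoothing, supertrials on epochs).
    unit_ids
        Length-``V`` unique unit identifiers (voxel linear indexes, channel
        names, or component indexes).
    space
        One of ``{"volume", "channel", "component"}``.
    geometry
        Source volume geometry, for ``space == "volume"``.
    provenance
        List of ``{"op": ..., **params}`` records appended by each operation.
    """

    patterns: np.ndarray
    condition_labels: np.ndarray
    run_ids: np.ndarray
    unit_ids: np.ndarray
    space: str = "channel"
    time_bins: np.ndarray | None = None
    trial_ids: np.ndarray | None = None
    geometry: VolumeGeometry | None = None
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise ValidationError("patterns must be a 2-D observations x units matrix")
        if not np.isfinite(self.patterns).all():
            raise ValidationError("patterns contain NaN or Inf values")
        n = self.patterns.shape[0]
        self.condition_labels = _as_1d("condition_labels", self.condition_labels, n).astype(str)
        self.run_ids = _as_1d("run_ids", self.run_ids, n)
        if self.time_bins is not None:
            self.time_bins = _as_1d("time_bins", self.time_bins, n).astype(int)
        if self.trial_ids is not None:
            self.trial_ids = _as_1d("trial_ids", self.trial_ids, n)
        self.unit_ids = _as_1d("unit_ids", self.unit_ids, self.patterns.shape[1])
        if len(np.unique(self.unit_ids)) != len(self.unit_ids):
            raise ValidationError("unit_ids must be unique")
        if self.space not in ("volume", "channel", "component"):
            raise ValidationError(f"unknown space {self.space!r}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_observations(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Condition names in order of first appearance."""
        _, idx = np.unique(self.condition_labels, return_index=True)
        return [self.condition_labels[i] for i in sorted(idx)]

    @property
    def is_time_resolved(self) -> bool:
        return self.time_bins is not None

    # -- derived views (never mutate self) ------------------------------------

    def with_patterns(self, patterns: np.ndarray, *, op: dict | None = None,
                      **overrides: Any) -> "PatternSet":
        """Copy with a new pattern matrix (same labels) and a provenance record."""
        new = replace(self, patterns=patterns, provenance=list(self.provenance),
                      **overrides)
        if op is not None:
            new.provenance.append(op)
        return new

    def take_observations(self, index: np.ndarray, *, op: dict | None = None) -> "PatternSet":
        new = PatternSet(
            patterns=self.patterns[index],
            condition_labels=self.condition_labels[index],
            run_ids=self.run_ids[index],
            time_bins=None if self.time_bins is None else self.time_bins[index],
            trial_ids=None if self.trial_ids is None else self.trial_ids[index],
            unit_ids=self.unit_ids,
            space=self.space,
            geometry=self.geometry,
            provenance=list(self.provenance),
        )
        if op is not None:
            new.provenance.append(op)
        return new

    def take_units(self, index: np.ndarray, *, op: dict | None = None) -> "PatternSet":
        new = replace(
            self,
            patterns=self.patterns[:, index],
            unit_ids=self.unit_ids[index],
            provenance=list(self.provenance),
        )
        if op is not None:
            new.provenance.append(op)
        return new

    def same_support(self, other: "PatternSet | TemplateSet") -> bool:
        """True when both objects share identical unit ids in the same order."""
        return (
            self.n_units == other.n_units
            and bool(np.all(np.asarray(self.unit_ids) == np.asarray(other.unit_ids)))
        )


@dataclass
class TemplateSet:
    """One canonical activity pattern per localizer condition.

    ``templates`` is ``(K, V)``; ``exemplars`` (optional) maps condition name
    to an observation stack for classifier training; ``runwise_estimates``
    (optional) is ``(n_runs, K, V)`` with ``run_ids`` naming the runs.
    """

    templates: np.ndarray
    condition_names: list[str]
    unit_ids: np.ndarray
    space: str = "channel"
    exemplars: dict[str, np.ndarray] | None = None
    runwise_estimates: np.ndarray | None = None
    run_ids: np.ndarray | None = None
    localizer_id: str | None = None
    time_window: tuple[int, int] | None = None
    geometry: VolumeGeometry | None = None
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2:
            raise ValidationError("templates must be a K x V matrix")
        self.condition_names = [str(c) for c in self.condition_names]
        if len(self.condition_names) != self.templates.shape[0]:
            raise ValidationError("condition_names length must equal template row count")
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValidationError("condition_names must be unique")
        self.unit_ids = _as_1d("unit_ids", self.unit_ids, self.templates.shape[1])
        if not np.isfinite(self.templates).all():
            raise ValidationError("templates contain NaN or Inf values")
        if self.runwise_estimates is not None:
            rw = np.asarray(self.runwise_estimates, dtype=float)
            if rw.ndim != 3 or rw.shape[1:] != self.templates.shape:
                raise ValidationError("runwise_estimates must be (n_runs, K, V)")
            if not np.allclose(rw.mean(axis=0), self.templates, atol=1e-8):
                raise ValidationError(
                    "runwise_estimates do not average to the canonical templates"
                )
            self.runwise_estimates = rw

    @property
    def n_conditions(self) -> int:
        return self.templates.shape[0]

    @property
    def n_units(self) -> int:
        return self.templates.shape[1]

    def template(self, condition: str) -> np.ndarray:
        try:
            k = self.condition_names.index(str(condition))
        except ValueError:
            raise ValidationError(f"no template for condition {condition!r}") from None
        return self.templates[k]

    def take_units(self, index: np.ndarray) -> "TemplateSet":
        return TemplateSet(
            templates=self.templates[:, index],
            condition_names=list(self.condition_names),
            unit_ids=self.unit_ids[index],
            space=self.space,
            exemplars=None if self.exemplars is None else {
                c: x[:, index] for c, x in self.exemplars.items()
            },
            runwise_estimates=None if self.runwise_estimates is None
            else self.runwise_estimates[:, :, index],
            run_ids=self.run_ids,
            localizer_id=self.localizer_id,
            time_window=self.time_window,
            geometry=self.geometry,
            provenance=list(self.provenance),
        )
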