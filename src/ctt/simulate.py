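"""Seeded synthetic localizer and main-task data with known ground truth.

The simulator produces the data structure canonical template tracking
assumes: a localizer whose trials are noisy realizations of K fixed
condition templates, and a main task whose trials are weighted mixtures of
those same templates plus noise.  The true templates, the mixing weights
and the noise covariance are returned as a :class:`GroundTruth` so that
parameter-recovery and bias tests can compare estimates against the latent
quantities.

Three modes are supported:

``pattern``
    Plain ``trials x units`` matrices (the default).
``volume``
    Units are the voxels of a 3-D grid; templates occupy only an axis-aligned
    ROI box, every other voxel is pure noise.
``epoch``
    Each trial is sampled at ``n_time_bins`` time bins; the template mixture
    is active only inside a boxcar ``active_window`` and zero outside.

Noise is Gaussian with stationary covariance ``sigma^2 [(1-rho) I + rho S]``
where ``S`` is a squared-exponential spatial kernel (length scale 2 units)
over unit index (pattern/epoch modes) or voxel coordinates (volume mode,
ROI voxels only; out-of-ROI voxels get independent noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .patterns import PatternSet, ValidationError, VolumeGeometry

__all__ = ["SimSpec", "GroundTruth", "generate_truth",
           "simulate_localizer", "simulate_main_task"]

_KERNEL_LENGTH_SCALE = 2.0  # units/voxels; fixed smooth-noise length scale


@dataclass
class SimSpec:
    """Full description of one simulated dataset pair (localizer + main).

    ``activation_weights`` maps each main-task condition name to a length-K
    weight vector over the template conditions; it is the ground truth the
    tracking stage tries to recover.
    """

    n_units: int = 100
    n_conditions: int = 2
    n_localizer_trials_per_condition: int = 16
    n_main_trials_per_condition: int = 16
    n_runs_localizer: int = 2
    n_chunks_main: int = 4
    noise_sd: float = 0.5
    spatial_corr: float = 0.0
    template_corr: float = 0.0
    activation_weights: Mapping[str, np.ndarray] | None = None
    baseline_shift_sd: float = 0.0
    mode: str = "pattern"
    volume_shape: tuple[int, int, int] | None = None
    roi_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    n_time_bins: int | None = None
    active_window: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_units": self.n_units,
            "n_conditions": self.n_conditions,
            "n_localizer_trials_per_condition": self.n_localizer_trials_per_condition,
            "n_main_trials_per_condition": self.n_main_trials_per_condition,
            "n_runs_localizer": self.n_runs_localizer,
            "n_chunks_main": self.n_chunks_main,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValidationError(f"{name} must be an integer >= 1, got {value!r}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.spatial_corr < 1.0:
            raise ValidationError(
                f"spatial_corr must lie in [0, 1), got {self.spatial_corr}")
        if self.n_conditions > 1:
            if not -1.0 < self.template_corr < 1.0:
                raise ValidationError(
                    f"template_corr must lie in (-1, 1), got {self.template_corr}")
            lower = -1.0 / (self.n_conditions - 1)
            if self.template_corr <= lower:
                raise ValidationError(
                    f"template_corr must exceed {lower:.4f} for "
                    f"{self.n_conditions} conditions to keep the correlation "
                    "matrix positive definite")
        if self.baseline_shift_sd < 0:
            raise ValidationError("baseline_shift_sd must be >= 0")
        if self.mode not in ("pattern", "volume", "epoch"):
            raise ValidationError(f"mode must be pattern|volume|epoch, got {self.mode!r}")
        if self.n_localizer_trials_per_condition % self.n_runs_localizer:
            raise ValidationError(
                "n_localizer_trials_per_condition must be divisible by "
                "n_runs_localizer for balanced runs")
        if self.n_main_trials_per_condition % self.n_chunks_main:
            raise ValidationError(
                "n_main_trials_per_condition must be divisible by n_chunks_main "
                "for balanced chunks")
        if self.mode == "volume":
            if self.volume_shape is None or self.roi_box is None:
                raise ValidationError("volume mode requires volume_shape and roi_box")
            shape = tuple(int(s) for s in self.volume_shape)
            box = tuple((int(a), int(b)) for a, b in self.roi_box)
            for axis, ((a, b), s) in enumerate(zip(box, shape)):
                if not (0 <= a < b <= s):
                    raise ValidationError(
                        f"roi_box axis {axis} range [{a}, {b}) not inside "
                        f"volume_shape extent {s}")
            self.volume_shape = shape
            self.roi_box = box
            if self.n_units != int(np.prod(shape)):
                raise ValidationError(
                    "n_units must equal prod(volume_shape) in volume mode")
        if self.mode == "epoch":
            if self.n_time_bins is None or self.active_window is None:
                raise ValidationError("epoch mode requires n_time_bins and active_window")
            t0, t1 = (int(t) for t in self.active_window)
            if not (0 <= t0 < t1 <= self.n_time_bins):
                raise ValidationError(
                    f"active_window [{t0}, {t1}) must lie inside "
                    f"[0, {self.n_time_bins})")
            self.active_window = (t0, t1)
        if self.activation_weights is not None:
            for cond, w in self.activation_weights.items():
                w = np.asarray(w, dtype=float)
                if w.shape != (self.n_conditions,):
                    raise ValidationError(
                        f"activation_weights[{cond!r}] has length {w.size}, "
                        f"expected {self.n_conditions}")

    @property
    def template_conditions(self) -> list[str]:
        return [f"cond{k}" for k in range(self.n_conditions)]

    def resolved_weights(self) -> dict[str, np.ndarray]:
        """Weight map with the identity default (each condition drives its own template)."""
        if self.activation_weights is not None:
            return {str(c): np.asarray(w, dtype=float)
                    for c, w in self.activation_weights.items()}
        eye = np.eye(self.n_conditions)
        return {c: eye[k] for k, c in enumerate(self.template_conditions)}

    @property
    def roi_unit_index(self) -> np.ndarray:
        """Linear (C-order) indexes of in-ROI voxels, or all units outside volume mode."""
        if self.mode != "volume":
            return np.arange(self.n_units)
        grid = np.zeros(self.volume_shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.roi_box
        grid[x0:x1, y0:y1, z0:z1] = True
        return np.flatnonzero(grid.ravel(order="C"))


@dataclass
class GroundTruth:
    """Latent quantities of one simulation: templates, weights, noise covariance.

    ``true_templates`` is ``K x V_signal`` where ``V_signal`` is the template
    support (all units, or the ROI voxels in volume mode).  ``noise_covariance``
    covers the same support.
    """

    true_templates: np.ndarray
    activation_weights: dict[str, np.ndarray]
    noise_covariance: np.ndarray
    seed: int
    signal_unit_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.true_templates = np.asarray(self.true_templates, dtype=float)
        if not np.isfinite(self.true_templates).all():
            raise ValidationError("true_templates contain non-finite values")
        cov = np.asarray(self.noise_covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError("noise_covariance must be symmetric")
        # positive definiteness; sigma = 0 gives the zero matrix, allowed
        if cov.size and not np.allclose(cov, 0):
            eigmin = np.linalg.eigvalsh(cov)[0]
            if eigmin <= -1e-10:
                raise ValidationError("noise_covariance must be positive semi-definite")
        self.noise_covariance = cov


def _branch(seed: int, *path: str | int) -> np.random.SeedSequence:
    """Independent named sub-stream of the dataset seed tree.

    Truth, localizer runs and main-task chunks each get their own branch so
    that regenerating one dataset never replays another's noise.
    """
    _BRANCHES = {"truth": 0, "localizer": 1, "main": 2}
    keys = [_BRANCHES[p] if isinstance(p, str) else int(p) for p in path]
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(keys))


def _spatial_kernel(coords: np.ndarray) -> np.ndarray:
    """Squared-exponential correlation kernel over unit coordinates."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * _KERNEL_LENGTH_SCALE**2))


def _noise_covariance(spec: SimSpec, n_signal: int) -> np.ndarray:
    sigma2 = spec.noise_sd**2
    if spec.spatial_corr == 0.0:
        return sigma2 * np.eye(n_signal)
    if spec.mode == "volume":
        coords = np.argwhere(np.ones(spec.volume_shape, dtype=bool))[spec.roi_unit_index]
        coords = coords.astype(float)
    else:
        coords = np.arange(n_signal, dtype=float)[:, None]
    S = _spatial_kernel(coords)
    rho = spec.spatial_corr
    return sigma2 * ((1.0 - rho) * np.eye(n_signal) + rho * S)


def generate_truth(spec: SimSpec) -> GroundTruth:
    """Draw the latent templates and noise covariance for a :class:`SimSpec`.

    Templates are built by mixing K i.i.d. standard-Gaussian unit vectors
    through the Cholesky factor of the K x K equicorrelation matrix with
    off-diagonal ``template_corr``, so the population pairwise correlation is
    exact by construction; each template is then standardized to zero mean
    and unit variance across units (which leaves pairwise sample
    correlations unchanged).
    """
    rng = np.random.default_rng(_branch(spec.seed, "truth"))
    signal_index = spec.roi_unit_index
    v = signal_index.size
    K = spec.n_conditions
    R = np.full((K, K), spec.template_corr)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    raw = L @ rng.standard_normal((K, v))
    # standardize rows: zero mean, unit variance across units
    raw = raw - raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    templates = raw / sd[:, None]
    cov = _noise_covariance(spec, v)
    return GroundTruth(
        true_templates=templates,
        activation_weights=spec.resolved_weights(),
        noise_covariance=cov,
        seed=spec.seed,
        signal_unit_index=signal_index,
    )


class _NoiseSampler:
    """Draws correlated noise on the template support, white noise elsewhere."""

    def __init__(self, truth: GroundTruth, spec: SimSpec):
        self.spec = spec
        self.signal_index = truth.signal_unit_index
        cov = truth.noise_covariance
        if cov.size and not np.allclose(cov, cov[0, 0] * np.eye(cov.shape[0])):
            self.chol = np.linalg.cholesky(
                cov + 1e-12 * np.eye(cov.shape[0]))
        else:
            self.chol = None  # iid shortcut

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        spec = self.spec
        out = rng.standard_normal((n, spec.n_units)) * spec.noise_sd
        if self.chol is not None:
            z = rng.standard_normal((n, self.signal_index.size))
            out[:, self.signal_index] = z @ self.chol.T
        return out


def _embed(templates: np.ndarray, spec: SimSpec, signal_index: np.ndarray) -> np.ndarray:
    """Place K x V_signal templates into the full unit space (zeros elsewhere)."""
    if signal_index.size == spec.n_units:
        return templates
    full = np.zeros((templates.shape[0], spec.n_units))
    full[:, signal_index] = templates
    return full


def _check_consistent(truth: GroundTruth, spec: SimSpec) -> None:
    if truth.true_templates.shape != (spec.n_conditions, truth.signal_unit_index.size):
        raise ValidationError("GroundTruth inconsistent with SimSpec shapes")
    for cond, w in truth.activation_weights.items():
        if np.asarray(w).shape != (spec.n_conditions,):
            raise ValidationError(
                f"activation_weights[{cond!r}] has length {np.asarray(w).size}, "
                f"expected {spec.n_conditions}")


def _geometry(spec: SimSpec) -> VolumeGeometry | None:
    if spec.mode != "volume":
        return None
    return VolumeGeometry(shape=spec.volume_shape, affine=np.eye(4))


def simulate_localizer(truth: GroundTruth, spec: SimSpec) -> PatternSet:
    """Localizer trials: each trial is its condition's true template plus noise.

    Trials are balanced across runs (equal count per condition in every run)
    and labeled with condition and run.  In epoch mode each trial contributes
    one observation per time bin, the template being present only inside the
    active window.
    """
    _check_consistent(truth, spec)
    sampler = _NoiseSampler(truth, spec)
    full_templates = _embed(truth.true_templates, spec, truth.signal_unit_index)
    per_run = spec.n_localizer_trials_per_condition // spec.n_runs_localizer
    conds = spec.template_conditions

    rows, labels, runs, bins, trials = [], [], [], [], []
    trial_counter = 0
    for run in range(spec.n_runs_localizer):
        rng = np.random.default_rng(_branch(spec.seed, "localizer", run))
        for k, cond in enumerate(conds):
            for _ in range(per_run):
                if spec.mode == "epoch":
                    t0, t1 = spec.active_window
                    sig = np.zeros((spec.n_time_bins, spec.n_units))
                    sig[t0:t1] = full_templates[k]
                    noise = sampler.draw(rng, spec.n_time_bins)
                    rows.append(sig + noise)
                    labels.extend([cond] * spec.n_time_bins)
                    runs.extend([run] * spec.n_time_bins)
                    bins.extend(range(spec.n_time_bins))
                    trials.extend([trial_counter] * spec.n_time_bins)
                else:
                    noise = sampler.draw(rng, 1)
                    rows.append(full_templates[k][None, :] + noise)
                    labels.append(cond)
                    runs.append(run)
                    trials.append(trial_counter)
                trial_counter += 1
    return PatternSet(
        patterns=np.vstack(rows),
        condition_labels=np.array(labels),
        run_ids=np.array(runs),
        time_bins=np.array(bins) if spec.mode == "epoch" else None,
        trial_ids=np.array(trials),
        unit_ids=np.arange(spec.n_units),
        space="volume" if spec.mode == "volume" else "channel",
        geometry=_geometry(spec),
        provenance=[{"op": "simulate_localizer", "seed": spec.seed}],
    )


def simulate_main_task(truth: GroundTruth, spec: SimSpec) -> PatternSet:
    """Main-task trials: weighted template mixtures plus noise and run shifts.

    Each trial of condition ``c`` carries signal ``sum_k w_ck template_k``
    (ground-truth mixing weights), plus a correlated noise draw and an
    optional per-chunk scalar baseline offset added to every unit.  In epoch
    mode the signal is a boxcar confined to the active window; in volume
    mode it occupies only the ROI voxels.
    """
    _check_consistent(truth, spec)
    shift_rng = np.random.default_rng(_branch(spec.seed, "main", 0))
    sampler = _NoiseSampler(truth, spec)
    full_templates = _embed(truth.true_templates, spec, truth.signal_unit_index)
    weights = truth.activation_weights
    per_chunk = spec.n_main_trials_per_condition // spec.n_chunks_main
    conds = list(weights.keys())
    shifts = shift_rng.normal(0.0, spec.baseline_shift_sd, size=spec.n_chunks_main) \
        if spec.baseline_shift_sd > 0 else np.zeros(spec.n_chunks_main)

    rows, labels, chunks, bins, trials = [], [], [], [], []
    trial_counter = 0
    for chunk in range(spec.n_chunks_main):
        rng = np.random.default_rng(_branch(spec.seed, "main", 1 + chunk))
        for cond in conds:
            w = np.asarray(weights[cond], dtype=float)
            signal = w @ full_templates
            for _ in range(per_chunk):
                if spec.mode == "epoch":
                    t0, t1 = spec.active_window
                    sig = np.zeros((spec.n_time_bins, spec.n_units))
                    sig[t0:t1] = signal
                    noise = sampler.draw(rng, spec.n_time_bins)
                    rows.append(sig + noise + shifts[chunk])
                    labels.extend([cond] * spec.n_time_bins)
                    chunks.extend([chunk] * spec.n_time_bins)
                    bins.extend(range(spec.n_time_bins))
                    trials.extend([trial_counter] * spec.n_time_bins)
                else:
                    noise = sampler.draw(rng, 1)
                    rows.append(signal[None, :] + noise + shifts[chunk])
                    labels.append(cond)
                    chunks.append(chunk)
                    trials.append(trial_counter)
                trial_counter += 1
    return PatternSet(
        patterns=np.vstack(rows),
        condition_labels=np.array(labels),
        run_ids=np.array(chunks),
        time_bins=np.array(bins) if spec.mode == "epoch" else None,
        trial_ids=np.array(trials),
        unit_ids=np.arange(spec.n_units),
        space="volume" if spec.mode == "volume" else "channel",
        geometry=_geometry(spec),
        provenance=[{"op": "simulate_main_task", "seed": spec.seed}],
    )
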