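"""Canonical template estimation and spatial/temporal support selection.

A canonical template is the mean localizer activity pattern of one
condition — the reference representation the main-task data is compared
against.  Support selection restricts where (ROI voxels) or when (time
window) the templates are defined; the same selection must be applied to
the main-task patterns before tracking.
"""

from __future__ import annotations

import numpy as np

from .patterns import PatternSet, TemplateSet, ValidationError

__all__ = ["estimate_templates", "select_roi", "select_time_window"]


def estimate_templates(loc: PatternSet, keep_exemplars: bool = False,
                       keep_runwise: bool = False,
                       localizer_id: str | None = None) -> TemplateSet:
    """Condition-mean canonical templates from a localizer PatternSet.

    With ``keep_runwise`` the template is the grand mean of per-run means
    (requires >= 2 runs), and the per-run estimates are retained for
    cross-validated estimators and the correlationability diagnostic.  With
    ``keep_exemplars`` the individual observations are retained per
    condition for classifier training.
    """
    conds = loc.conditions
    if not conds:
        raise ValidationError("localizer PatternSet has no observations")
    runs = np.unique(loc.run_ids)
    if keep_runwise and runs.size < 2:
        raise ValidationError("keep_runwise requires at least 2 localizer runs")

    K, V = len(conds), loc.n_units
    exemplars: dict[str, np.ndarray] = {}
    if keep_runwise:
        runwise = np.empty((runs.size, K, V))
        for r, run in enumerate(runs):
            for k, cond in enumerate(conds):
                idx = np.flatnonzero((loc.condition_labels == cond)
                                     & (loc.run_ids == run))
                if idx.size == 0:
                    raise ValidationError(
                        f"condition {cond!r} has no observations in run {run!r}")
                runwise[r, k] = loc.patterns[idx].mean(axis=0)
        templates = runwise.mean(axis=0)
    else:
        runwise = None
        templates = np.empty((K, V))
        for k, cond in enumerate(conds):
            idx = np.flatnonzero(loc.condition_labels == cond)
            if idx.size == 0:
                raise ValidationError(f"condition {cond!r} has no observations")
            templates[k] = loc.patterns[idx].mean(axis=0)
    if keep_exemplars:
        for cond in conds:
            exemplars[cond] = loc.patterns[loc.condition_labels == cond].copy()

    return TemplateSet(
        templates=templates,
        condition_names=conds,
        unit_ids=loc.unit_ids,
        space=loc.space,
        exemplars=exemplars if keep_exemplars else None,
        runwise_estimates=runwise,
        run_ids=runs if keep_runwise else None,
        localizer_id=localizer_id,
        geometry=loc.geometry,
        provenance=loc.provenance + [{"op": "estimate_templates",
                                      "keep_runwise": keep_runwise,
                                      "keep_exemplars": keep_exemplars}],
    )


def select_roi(ps: PatternSet, mask: np.ndarray) -> PatternSet:
    """Restrict a volumetric PatternSet to the in-mask voxels.

    ``mask`` is a boolean (or 0/1) array with the source volume's shape.
    Unit ids (linear voxel indexes) are preserved so statistic maps can be
    written back into the volume later.
    """
    if ps.space != "volume" or ps.geometry is None:
        raise ValidationError("select_roi requires a volumetric PatternSet")
    mask = np.asarray(mask)
    if mask.shape != ps.geometry.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume shape {ps.geometry.shape}")
    flat = mask.ravel(order="C").astype(bool)
    keep_linear = np.flatnonzero(flat)
    if keep_linear.size == 0:
        raise ValidationError("mask selects no voxels")
    # unit_ids are linear voxel indexes; keep those inside the mask
    unit_pos = {u: i for i, u in enumerate(np.asarray(ps.unit_ids))}
    cols = [unit_pos[u] for u in keep_linear if u in unit_pos]
    if not cols:
        raise ValidationError("mask does not overlap the PatternSet's voxels")
    return ps.take_units(np.asarray(cols), op={"op": "select_roi",
                                               "n_voxels": len(cols)})


def select_time_window(ps: PatternSet, window: tuple[int, int],
                       collapse: bool = False) -> PatternSet:
    """Keep time bins in the half-open window ``[t_start, t_end)``.

    With ``collapse`` the in-window bins of each trial are averaged to a
    single pattern per trial (the "theoretically informed time window"
    strategy); otherwise the time axis is kept.
    """
    if not ps.is_time_resolved:
        raise ValidationError("select_time_window requires epoch data")
    t0, t1 = int(window[0]), int(window[1])
    if t1 <= t0:
        raise ValidationError(f"empty time window [{t0}, {t1})")
    present = np.unique(ps.time_bins)
    if t0 < present.min() or t1 > present.max() + 1:
        raise ValidationError(
            f"window [{t0}, {t1}) outside sampled bins "
            f"[{present.min()}, {present.max() + 1})")
    keep = np.flatnonzero((ps.time_bins >= t0) & (ps.time_bins < t1))
    if keep.size == 0:
        raise ValidationError(f"no observations inside window [{t0}, {t1})")
    out = ps.take_observations(keep, op={"op": "select_time_window",
                                         "window": [t0, t1],
                                         "collapse": collapse})
    if not collapse:
        return out
    if out.trial_ids is None:
        raise ValidationError("collapse requires trial_ids")
    trials = []
    seen = set()
    for t in out.trial_ids:
        if t not in seen:
            seen.add(t)
            trials.append(t)
    rows, conds, runs, tids = [], [], [], []
    for t in trials:
        idx = np.flatnonzero(out.trial_ids == t)
        rows.append(out.patterns[idx].mean(axis=0))
        conds.append(out.condition_labels[idx[0]])
        runs.append(out.run_ids[idx[0]])
        tids.append(t)
    return PatternSet(
        patterns=np.vstack(rows),
        condition_labels=np.array(conds),
        run_ids=np.array(runs),
        time_bins=None,
        trial_ids=np.array(tids),
        unit_ids=out.unit_ids,
        space=out.space,
        geometry=out.geometry,
        provenance=out.provenance,
    )
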