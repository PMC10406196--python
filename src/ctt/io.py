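"""Readers and writers: HDF5 pattern containers, TSV tables, NIfTI volumes,
JSON summaries and the output manifest.

Container schema (HDF5): ``/patterns`` (observations x units), ``/labels/*``
(condition, run, optional time_bin / trial), ``/units/unit_ids``, root
attributes ``schema_version``, ``kind`` and ``space``.  TemplateSets use
``/templates`` plus ``/condition_names`` and optional ``/runwise`` /
``/exemplars/<condition>`` groups.  Simulated ground truth is stored in its
own file, never mixed into analysis inputs.

Conventions enforced everywhere: voxel unit ids are 0-based C-order linear
indexes into the volume; time windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .mapping import StatMap, TemporalGeneralizationMatrix
from .patterns import PatternSet, TemplateSet, ValidationError, VolumeGeometry
from .simulate import GroundTruth
from .tracking import TrackingResult

__all__ = [
    "save_pattern_container",
    "load_pattern_container",
    "save_ground_truth",
    "load_ground_truth",
    "read_volume",
    "write_volume",
    "read_pattern_tsv",
    "write_results",
]

SCHEMA_VERSION = "1"


def _write_strings(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.asarray(values, dtype=object),
                         dtype=h5py.string_dtype())


def _read_strings(ds: h5py.Dataset) -> np.ndarray:
    return np.asarray([v.decode() if isinstance(v, bytes) else str(v)
                       for v in ds[()]])


def save_pattern_container(path, obj: "PatternSet | TemplateSet") -> Path:
    """Write a PatternSet or TemplateSet to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["space"] = obj.space
        f.attrs["provenance"] = json.dumps(obj.provenance, default=str)
        units = f.create_group("units")
        uid = np.asarray(obj.unit_ids)
        if uid.dtype.kind in "US O":
            _write_strings(units, "unit_ids", uid)
        else:
            units.create_dataset("unit_ids", data=uid)
        if obj.geometry is not None:
            g = f.create_group("geometry")
            g.create_dataset("affine", data=obj.geometry.affine)
            g.attrs["shape"] = obj.geometry.shape
        if isinstance(obj, PatternSet):
            f.attrs["kind"] = "patterns"
            f.create_dataset("patterns", data=obj.patterns)
            labels = f.create_group("labels")
            _write_strings(labels, "condition", obj.condition_labels)
            labels.create_dataset("run", data=np.asarray(obj.run_ids, dtype=np.int64))
            if obj.time_bins is not None:
                labels.create_dataset("time_bin", data=obj.time_bins)
            if obj.trial_ids is not None:
                labels.create_dataset(
                    "trial", data=np.asarray(obj.trial_ids, dtype=np.int64))
        elif isinstance(obj, TemplateSet):
            f.attrs["kind"] = "templates"
            f.create_dataset("templates", data=obj.templates)
            _write_strings(f, "condition_names", obj.condition_names)
            if obj.runwise_estimates is not None:
                f.create_dataset("runwise", data=obj.runwise_estimates)
                f.create_dataset("run_ids",
                                 data=np.asarray(obj.run_ids, dtype=np.int64))
            if obj.exemplars is not None:
                ex = f.create_group("exemplars")
                for cond, x in obj.exemplars.items():
                    ex.create_dataset(str(cond), data=x)
        else:
            raise ValidationError(f"cannot serialize object of type {type(obj)}")
    return path


def _geometry_from(f: h5py.File) -> VolumeGeometry | None:
    if "geometry" not in f:
        return None
    g = f["geometry"]
    return VolumeGeometry(shape=tuple(int(s) for s in g.attrs["shape"]),
                          affine=g["affine"][()])


def load_pattern_container(path) -> "PatternSet | TemplateSet":
    """Read a pattern/template container, validating its schema."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported container schema version {version!r} "
                f"(expected {SCHEMA_VERSION!r})")
        kind = f.attrs.get("kind")
        space = str(f.attrs.get("space", "channel"))
        if "units" not in f or "unit_ids" not in f["units"]:
            raise ValidationError("container is missing the units/unit_ids dataset")
        uid = f["units/unit_ids"]
        unit_ids = _read_strings(uid) if uid.dtype.kind in "SO" else uid[()]
        provenance = json.loads(f.attrs.get("provenance", "[]"))
        geometry = _geometry_from(f)
        if kind == "patterns":
            for req in ("patterns", "labels"):
                if req not in f:
                    raise ValidationError(f"container is missing group {req!r}")
            if "condition" not in f["labels"]:
                raise ValidationError("container is missing labels/condition")
            if "run" not in f["labels"]:
                raise ValidationError("container is missing labels/run")
            return PatternSet(
                patterns=f["patterns"][()],
                condition_labels=_read_strings(f["labels/condition"]),
                run_ids=f["labels/run"][()],
                time_bins=f["labels/time_bin"][()] if "time_bin" in f["labels"] else None,
                trial_ids=f["labels/trial"][()] if "trial" in f["labels"] else None,
                unit_ids=unit_ids,
                space=space,
                geometry=geometry,
                provenance=provenance,
            )
        if kind == "templates":
            if "templates" not in f or "condition_names" not in f:
                raise ValidationError(
                    "template container needs templates and condition_names")
            exemplars = None
            if "exemplars" in f:
                exemplars = {c: f["exemplars"][c][()] for c in f["exemplars"]}
            return TemplateSet(
                templates=f["templates"][()],
                condition_names=list(_read_strings(f["condition_names"])),
                unit_ids=unit_ids,
                space=space,
                exemplars=exemplars,
                runwise_estimates=f["runwise"][()] if "runwise" in f else None,
                run_ids=f["run_ids"][()] if "run_ids" in f else None,
                geometry=geometry,
                provenance=provenance,
            )
        raise ValidationError(f"unknown container kind {kind!r}")


def save_ground_truth(path, truth: GroundTruth) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "ground_truth"
        g = f.create_group("ground_truth")
        g.create_dataset("true_templates", data=truth.true_templates)
        g.create_dataset("noise_covariance", data=truth.noise_covariance)
        g.create_dataset("signal_unit_index", data=truth.signal_unit_index)
        g.attrs["seed"] = truth.seed
        w = g.create_group("activation_weights")
        for cond, vec in truth.activation_weights.items():
            w.create_dataset(str(cond), data=np.asarray(vec, dtype=float))
    return path


def load_ground_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "ground_truth":
            raise ValidationError("not a ground-truth container")
        g = f["ground_truth"]
        return GroundTruth(
            true_templates=g["true_templates"][()],
            activation_weights={c: g["activation_weights"][c][()]
                                for c in g["activation_weights"]},
            noise_covariance=g["noise_covariance"][()],
            seed=int(g.attrs["seed"]),
            signal_unit_index=g["signal_unit_index"][()],
        )


# -- NIfTI --------------------------------------------------------------------

def read_volume(path, mask_path=None, labels: pd.DataFrame | None = None
                ) -> PatternSet:
    """4-D NIfTI -> PatternSet: 4th dimension are observations, in-mask
    voxels the units (0-based C-order linear indexes).

    ``labels``, when given, is a table with one row per volume and columns
    ``condition`` and ``run`` (optional ``time_bin``, ``trial``).
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValidationError(f"expected a 3-D/4-D NIfTI, got {data.ndim}-D")
    shape = data.shape[:3]
    affine = img.affine
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if tuple(mimg.shape[:3]) != tuple(shape):
            raise ValidationError(
                f"mask shape {tuple(mimg.shape[:3])} != volume shape {tuple(shape)}")
        if not np.allclose(mimg.affine, affine, atol=1e-4):
            raise ValidationError("mask affine does not match the volume affine")
        mask = np.asarray(mimg.get_fdata()) > 0
    else:
        mask = np.ones(shape, dtype=bool)
    flat = data.reshape(-1, data.shape[3], order="C")  # voxels x obs
    keep = np.flatnonzero(mask.ravel(order="C"))
    patterns = flat[keep].T  # obs x voxels
    bad = ~np.isfinite(patterns)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} non-finite voxel values inside the mask")
    n_obs = patterns.shape[0]
    if labels is not None:
        labels = pd.DataFrame(labels)
        if len(labels) != n_obs:
            raise ValidationError(
                f"labels table has {len(labels)} rows for {n_obs} volumes")
        cond = labels["condition"].to_numpy()
        run = labels["run"].to_numpy() if "run" in labels else np.zeros(n_obs, int)
        tb = labels["time_bin"].to_numpy() if "time_bin" in labels else None
        tr = labels["trial"].to_numpy() if "trial" in labels else None
    else:
        cond = np.array([f"vol{i}" for i in range(n_obs)])
        run = np.zeros(n_obs, dtype=int)
        tb = tr = None
    return PatternSet(
        patterns=patterns, condition_labels=cond, run_ids=run,
        time_bins=tb, trial_ids=tr, unit_ids=keep, space="volume",
        geometry=VolumeGeometry(shape=tuple(shape), affine=affine),
        provenance=[{"op": "read_volume", "path": str(path)}],
    )


def write_volume(path, ps_or_map, fill=np.nan) -> Path:
    """Write a volumetric PatternSet (4-D) or StatMap (3-D) as NIfTI."""
    import nibabel as nib

    path = Path(path)
    if isinstance(ps_or_map, StatMap):
        if ps_or_map.kind != "volume":
            raise ValidationError("only volume StatMaps can be written as NIfTI")
        affine = (ps_or_map.geometry.affine if ps_or_map.geometry is not None
                  else np.eye(4))
        nib.save(nib.Nifti1Image(ps_or_map.values.astype(np.float64), affine),
                 str(path))
        return path
    ps = ps_or_map
    if ps.space != "volume" or ps.geometry is None:
        raise ValidationError("PatternSet must be volumetric to write NIfTI")
    vol = np.full(ps.geometry.shape + (ps.n_observations,), fill, dtype=np.float64)
    flat = vol.reshape(-1, ps.n_observations, order="C")
    flat[np.asarray(ps.unit_ids, dtype=np.int64)] = ps.patterns.T
    nib.save(nib.Nifti1Image(vol, ps.geometry.affine), str(path))
    return path


# -- TSV ----------------------------------------------------------------------

_LABEL_COLUMNS = ("condition", "run", "time_bin", "trial")


def read_pattern_tsv(path) -> PatternSet:
    """Pattern table: label columns + one column per unit, tab-separated."""
    df = pd.read_csv(path, sep="\t")
    if "condition" not in df.columns:
        raise ValidationError("pattern TSV is missing the 'condition' column")
    if "run" not in df.columns:
        raise ValidationError("pattern TSV is missing the 'run' column")
    unit_cols = [c for c in df.columns if c not in _LABEL_COLUMNS]
    if not unit_cols:
        raise ValidationError("pattern TSV has no unit columns")
    return PatternSet(
        patterns=df[unit_cols].to_numpy(dtype=float),
        condition_labels=df["condition"].to_numpy(),
        run_ids=df["run"].to_numpy(),
        time_bins=df["time_bin"].to_numpy() if "time_bin" in df else None,
        trial_ids=df["trial"].to_numpy() if "trial" in df else None,
        unit_ids=np.asarray(unit_cols),
        space="channel",
        provenance=[{"op": "read_pattern_tsv", "path": str(path)}],
    )


def write_pattern_tsv(path, ps: PatternSet) -> Path:
    path = Path(path)
    df = pd.DataFrame(ps.patterns, columns=[str(u) for u in ps.unit_ids])
    df.insert(0, "condition", ps.condition_labels)
    df.insert(1, "run", ps.run_ids)
    if ps.time_bins is not None:
        df.insert(2, "time_bin", ps.time_bins)
    if ps.trial_ids is not None:
        df.insert(2, "trial", ps.trial_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


# -- results + manifest -------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable hash of a canonicalized (sorted-keys JSON) configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def write_results(results: dict[str, Any], out_dir,
                  config: dict | None = None, seed: int | None = None) -> dict:
    """Write heterogeneous result objects and a manifest tying them together.

    Dispatch by type: StatMap -> NIfTI (volume) or TSV (time course);
    TemporalGeneralizationMatrix / DataFrame / TrackingResult -> TSV;
    dict -> JSON; PatternSet/TemplateSet -> HDF5.  The manifest lists every
    artifact with the config hash and seed, so each file is traceable to
    the configuration that produced it.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory {out} is not writable: {exc}")

    artifacts = []
    for name, obj in results.items():
        if isinstance(obj, StatMap):
            if obj.kind == "volume":
                fname = f"{name}.nii.gz"
                write_volume(out / fname, obj)
            else:
                fname = f"{name}.tsv"
                pd.DataFrame({"time_bin": obj.bins, "value": obj.values}) \
                    .to_csv(out / fname, sep="\t", index=False)
        elif isinstance(obj, TemporalGeneralizationMatrix):
            fname = f"{name}.tsv"
            pd.DataFrame(obj.values,
                         index=pd.Index(obj.localizer_bins, name="localizer_bin"),
                         columns=[str(b) for b in obj.main_bins]) \
                .to_csv(out / fname, sep="\t")
        elif isinstance(obj, TrackingResult):
            fname = f"{name}.tsv"
            obj.to_frame().to_csv(out / fname, sep="\t", index=False)
        elif isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            obj.to_csv(out / fname, sep="\t", index=False)
        elif isinstance(obj, (PatternSet, TemplateSet)):
            fname = f"{name}.h5"
            save_pattern_container(out / fname, obj)
        elif isinstance(obj, dict):
            fname = f"{name}.json"
            (out / fname).write_text(
                json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
        else:
            raise ValidationError(
                f"no writer for result {name!r} of type {type(obj).__name__}")
        artifacts.append({"name": name, "path": fname,
                          "type": type(obj).__name__})

    manifest = {
        "artifacts": artifacts,
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "schema_version": SCHEMA_VERSION,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    return manifest
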