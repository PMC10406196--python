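"""End-to-end pipeline: simulate (or load) -> extract -> templates -> track
-> group inference -> diagnostics, with all artifacts written through the
manifest.  This is what ``ctt run`` executes.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .diagnostics import reliability_report
from .extraction import make_supertrials, smooth_temporal
from .inference import cluster_correct, permutation_test, wilcoxon_signed_rank
from .io import load_pattern_container, write_results
from .mapping import StatMap
from .patterns import PatternSet, ValidationError
from .simulate import SimSpec, generate_truth, simulate_localizer, simulate_main_task
from .templates import estimate_templates
from .tracking import relative_activation, similarity_index

__all__ = ["run_pipeline"]

log = logging.getLogger("ctt")


def _subject_datasets(config: AnalysisConfig, subject: int
                      ) -> tuple[PatternSet, PatternSet]:
    if config.simulate:
        spec = SimSpec(**{**config.simulate, "seed": int(config.seed) + subject})
        truth = generate_truth(spec)
        return simulate_localizer(truth, spec), simulate_main_task(truth, spec)
    loc = load_pattern_container(config.paths["localizer"])
    main = load_pattern_container(config.paths["main"])
    if not isinstance(loc, PatternSet) or not isinstance(main, PatternSet):
        raise ValidationError("paths.localizer and paths.main must be PatternSets")
    return loc, main


def _extract(ps: PatternSet, config: AnalysisConfig, seed: int) -> PatternSet:
    opts = config.extraction
    k = int(opts.get("supertrial_k", 1))
    if k > 1:
        ps = make_supertrials(ps, k, seed=seed)
    w = int(opts.get("smoothing_window", 1))
    if w > 1 and ps.is_time_resolved:
        ps = smooth_temporal(ps, w)
    return ps


def _subject_index(config: AnalysisConfig, subject: int):
    """Per-subject relative activation index: scalar, or per-time-bin vector."""
    loc, main = _subject_datasets(config, subject)
    loc = _extract(loc, config, seed=config.seed + subject)
    main = _extract(main, config, seed=config.seed + subject)
    topts = config.tracking
    metric = topts.get("metric", "pearson")
    target = topts.get("target")
    baseline = topts.get("baseline")
    if target is None or baseline is None:
        conds = sorted(set(loc.condition_labels))
        if len(conds) < 2:
            raise ValidationError("need target and baseline conditions to track")
        target, baseline = conds[0], conds[1]
    keep_runwise = np.unique(loc.run_ids).size >= 2
    ts = estimate_templates(loc, keep_runwise=keep_runwise)
    tr = similarity_index(main, ts, metric=metric)
    tr = relative_activation(tr, target, baseline)
    rel = tr.relative_indexes[:, -1]
    # the group hypothesis concerns trials expected to reactivate the target
    # template; restrict to that main condition when it exists in the labels
    main_cond = topts.get("main_condition", target)
    keep = main.condition_labels == str(main_cond)
    if not keep.any():
        keep = np.ones(main.n_observations, dtype=bool)
    if main.is_time_resolved:
        bins = np.unique(main.time_bins)
        values = np.array([rel[keep & (main.time_bins == b)].mean() for b in bins])
        return values, bins, ts, tr
    return float(rel[keep].mean()), None, ts, tr


def run_pipeline(config: AnalysisConfig, output_dir=None) -> dict:
    """Run the configured analysis for every subject and write all outputs.

    Returns the manifest.  Outputs: per-subject relative indexes (TSV),
    group statistics (JSON: sign-flip permutation and Wilcoxon), a group
    time-course map plus cluster table for epoch data, and template
    reliability diagnostics for the first subject.
    """
    out = output_dir or config.output_dir
    if out is None:
        raise ValidationError("no output directory configured")
    t_start = time.monotonic()
    stage_log: list[str] = [
        f"tracking: {config.tracking}",
        f"extraction: {config.extraction}",
        f"inference: {config.inference}",
    ]
    n_sub = int(config.n_subjects)
    subject_values = []
    bins = None
    first_ts = first_tr = None
    for s in range(n_sub):
        value, b, ts, tr = _subject_index(config, s)
        if s == 0:
            first_ts, first_tr = ts, tr
            bins = b
        subject_values.append(value)
        log.info("subject %d tracked", s)
    data = np.asarray(subject_values)
    stage_log.append(f"tracking done: {n_sub} subjects, "
                     f"{time.monotonic() - t_start:.2f}s")

    iopts = config.inference
    n_perm = int(iopts.get("n_perm", 1000))
    alternative = iopts.get("alternative", "greater")
    perm = permutation_test(data if data.ndim == 2 else data[:, None],
                            scheme="group_sign_flip", n_perm=n_perm,
                            seed=int(config.seed),
                            statistic=iopts.get("statistic", "mean"),
                            alternative=alternative)
    group_summary: dict = {
        "n_subjects": n_sub,
        "alternative": alternative,
        "permutation": {
            "scheme": "group_sign_flip",
            "n_permutations": perm.n_permutations,
            "exhaustive": perm.exhaustive,
            "min_p": float(perm.p_values.min()),
        },
        **perm.null_summary(),
    }
    if data.ndim == 1 and n_sub >= 5 and np.any(data != 0):
        wres = wilcoxon_signed_rank(data, mu=0.0, alternative=alternative)
        group_summary["wilcoxon"] = {
            "statistic": wres.statistic, "p_value": wres.p_value,
            "n_used": wres.n_used, "method": wres.method,
        }
        group_summary["permutation"]["p_value"] = float(perm.p_values[0])
        group_summary["group_mean_relative_index"] = float(data.mean())

    results: dict = {}
    if data.ndim == 2:
        df = pd.DataFrame(data, columns=[f"bin{b}" for b in bins])
        df.insert(0, "subject", np.arange(n_sub))
        results["subject_indexes"] = df
        group_map = StatMap(values=data.mean(axis=0), kind="time",
                            statistic="group_mean_relative_index", bins=bins)
        results["group_timecourse"] = group_map
        cl = cluster_correct(
            perm.statistic, perm.null_distribution,
            forming_threshold=("p", float(iopts.get("forming_alpha", 0.05))),
            connectivity=int(iopts.get("connectivity", 6)),
            cluster_stat=iopts.get("cluster_stat", "size"),
            exhaustive=perm.exhaustive)
        table = cl.cluster_table.copy()
        table["members"] = table["members"].apply(
            lambda m: ",".join(str(i) for i in m))
        results["cluster_table"] = table
        group_summary["n_clusters"] = int(len(table))
        if len(table):
            group_summary["min_cluster_p_fwe"] = float(table["p_fwe"].min())
    else:
        results["subject_indexes"] = pd.DataFrame(
            {"subject": np.arange(n_sub), "relative_index": data})

    results["group_summary"] = group_summary
    results["tracking_subject0"] = first_tr
    target = config.tracking.get("target", first_ts.condition_names[0])
    col_indexes = {c: first_tr.column(c) for c in first_ts.condition_names}
    try:
        rel_report = reliability_report(first_ts, col_indexes)
        results["diagnostics"] = rel_report.as_dict()
    except ValidationError as exc:
        results["diagnostics"] = {"error": str(exc)}
    log.info("group inference done (target %s)", target)
    hashed = config.as_dict()
    # where the results land (and log verbosity) does not affect them
    hashed.pop("output_dir", None)
    hashed.pop("verbosity", None)
    manifest = write_results(results, out, config=hashed, seed=int(config.seed))
    stage_log.append(f"inference + write done: {time.monotonic() - t_start:.2f}s "
                     f"total, {len(manifest['artifacts'])} artifacts")
    # wall-clock timings live here, never in the manifest, so result files
    # stay bit-reproducible across runs
    (Path(out) / "ctt.log").write_text("\n".join(stage_log) + "\n")
    return manifest
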