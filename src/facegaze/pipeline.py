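"""End-to-end analysis: raw gaze streams to report tables.

``analyze_trials`` is the in-memory core: it consumes per-trial streams
plus trial metadata and produces the full report bundle — per-trial
measures, by-items norms, time-course tables with advantage profiles,
categorization tables, and by-items ANOVA/contrast/letter reports.
``run_pipeline`` wraps it with file input/output and a structured run
log.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .categorization import confusion_matrix, hits_and_rts
from .events import detect_fixations_ivt
from .gaze_io import RunConfig, read_gaze_file, read_trials_file
from .geometry import EXPRESSIONS, ROI_LABELS
from .metrics import aggregate_by_items, trial_metrics
from .stats import bonferroni_pairwise, compact_letter_display, oneway_anova
from .timecourse import advantage_report, bin_gaze_proportions, timecourse_by_items

__all__ = ["analyze_trials", "run_pipeline", "items_anova_report",
           "run_synthetic_study"]

#: by-items measures reported per region in the norm-table analogue
MEASURES = ("p_first", "p_entry", "gaze", "nfix")


def _measure_column(measure: str, roi: str) -> str:
    return {"p_first": f"p_first_{roi}", "p_entry": f"p_entry_{roi}",
            "gaze": f"gaze_{roi}_ms", "nfix": f"nfix_{roi}"}[measure]


def items_anova_report(item_norms: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-way by-items ANOVAs across expressions, per measure x region.

    For each measure and region: the omnibus F test with partial
    eta-squared, then Bonferroni pairwise contrasts pooled on its error
    term, summarised as per-expression means, SDs and letter codes
    (groups sharing a letter do not differ significantly).
    """
    rows = []
    present = [e for e in EXPRESSIONS if e in set(item_norms["expression"])]
    for measure in MEASURES:
        for roi in ROI_LABELS:
            col = _measure_column(measure, roi)
            groups = {e: item_norms.loc[item_norms["expression"] == e, col]
                      .dropna().to_numpy() for e in present}
            if any(len(v) < 2 for v in groups.values()):
                continue
            res = oneway_anova(groups, effect=f"{measure}:{roi}")
            contrasts = bonferroni_pairwise(groups, res.ms_error,
                                            res.df_error, alpha)
            means = {e: float(groups[e].mean()) for e in present}
            letters = compact_letter_display(contrasts, means)
            row = {"measure": measure, "roi": roi, "F": res.F,
                   "df_num": res.df_num, "df_den": res.df_den, "p": res.p,
                   "partial_eta_sq": res.partial_eta_sq}
            for e in present:
                row[f"{e}_mean"] = means[e]
                row[f"{e}_sd"] = float(groups[e].std(ddof=1))
                row[f"{e}_letters"] = letters[e]
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_trials(
    stream_items: Iterable[tuple[Mapping, pd.DataFrame]],
    config: RunConfig,
) -> dict[str, object]:
    """Run the full analysis over ``(trial_metadata, stream)`` pairs.

    Trial metadata must carry ``trial_id``, ``stimulus_id`` and
    ``expression`` (``participant``, ``response``, ``rt_ms`` enable the
    categorization tables).  Trials too short for the 10-bin time course
    are analysed for the other measures and skipped, with a warning, in
    the binning.  Returns the report bundle as a dict of DataFrames plus
    a ``log`` dict of parameters and counts.
    """
    rois = config.resolve_rois()
    center = config.resolve_center()
    metric_rows = []
    bin_rows = []
    n_fix = 0
    short_trials = []
    for meta, stream in stream_items:
        seg = detect_fixations_ivt(stream, config.screen,
                                   config.velocity_threshold,
                                   config.min_fixation_ms, rois,
                                   config.smoothing_window)
        n_fix += int((seg.events["kind"] == "fixation").sum())
        rec = dict(meta)
        rec.update(trial_metrics(seg, center, config.screen,
                                 config.center_radius_deg))
        metric_rows.append(rec)
        try:
            bins = bin_gaze_proportions(seg, config.bin_ms, config.n_bins)
        except ValueError:
            short_trials.append(meta["trial_id"])
            continue
        bins.insert(0, "trial_id", meta["trial_id"])
        bins.insert(1, "stimulus_id", meta["stimulus_id"])
        bins.insert(2, "expression", meta["expression"])
        bin_rows.append(bins)
    if short_trials:
        warnings.warn(f"{len(short_trials)} trial(s) too short for the "
                      f"time course: {short_trials[:5]}...")
    trial_table = pd.DataFrame(metric_rows)
    bundle: dict[str, object] = {"trial_metrics": trial_table}
    bundle["item_norms"] = aggregate_by_items(trial_table)
    bundle["anova_report"] = items_anova_report(bundle["item_norms"],
                                                config.alpha)
    if bin_rows:
        trial_bins = pd.concat(bin_rows, ignore_index=True)
        items = timecourse_by_items(trial_bins)
        bundle["timecourse_items"] = items
        n_per_expr = items.groupby("expression")["stimulus_id"].nunique()
        if len(n_per_expr) >= 2 and n_per_expr.min() >= 2:
            bundle["advantage"] = advantage_report(items, config.alpha,
                                                   config.n_bins)
    if "response" in trial_table.columns and trial_table["response"].notna().all():
        resp = trial_table.rename(columns={"expression": "stimulus_expression"})
        cm = confusion_matrix(resp, by_items=True)
        bundle["confusion"] = cm.to_frame(percent=True)
        bundle["hits_rts"] = hits_and_rts(resp)
    bundle["log"] = {
        "version": __version__,
        "parameters": {
            "velocity_threshold": config.velocity_threshold,
            "min_fixation_ms": config.min_fixation_ms,
            "min_blink_ms": config.min_blink_ms,
            "bin_ms": config.bin_ms,
            "n_bins": config.n_bins,
            "alpha": config.alpha,
            "center_radius_deg": config.center_radius_deg,
            "seed": config.seed,
        },
        "trials_read": len(trial_table),
        "fixations_detected": n_fix,
        "trials_excluded_from_timecourse": len(short_trials),
    }
    return bundle


def run_synthetic_study(
    n_models: int,
    n_participants: int,
    seed: int,
    profiles: Mapping | None = None,
    run_config: RunConfig | None = None,
    sim_config=None,
    confusion_model=None,
) -> dict[str, object]:
    """Simulate a full study and analyse it in one pass.

    Generates ``n_models x 6`` stimuli for ``n_participants`` observers
    under the given (or default) attention profiles and feeds each trial
    straight into the analysis, so raw streams never accumulate in
    memory.  Returns the :func:`analyze_trials` bundle.
    """
    from .geometry import stimulus_registry
    from .simulate import (SimulationConfig, default_profiles, default_setup,
                           iter_experiment)
    from .gaze_io import norms_confusion_model

    screen, _face_box, rois, default_sim = default_setup()
    sim_config = sim_config or default_sim
    run_config = run_config or RunConfig(screen=screen)
    profiles = profiles or default_profiles()
    confusion_model = confusion_model or norms_confusion_model()
    registry = stimulus_registry(n_models)
    pairs = ((meta, trial.stream) for meta, trial in iter_experiment(
        n_participants, registry, profiles, confusion_model, sim_config,
        rois, screen, seed))
    return analyze_trials(pairs, run_config)


def run_pipeline(
    config: RunConfig,
    gaze_path: str | Path,
    trials_path: str | Path,
    out_dir: str | Path,
) -> dict[str, object]:
    """File-to-file pipeline: read, analyse, write the report bundle.

    Every table is written as CSV into ``out_dir`` next to a
    ``run_log.json`` recording parameters and counts.  The run is
    deterministic given its inputs and configuration.
    """
    streams = read_gaze_file(gaze_path)
    trials = read_trials_file(trials_path)
    unknown = set(trials["trial_id"]) - set(streams)
    if unknown:
        raise ValueError(f"trials without gaze streams: {sorted(unknown)[:5]}")

    trial_rows = trials.to_dict("records")
    bundle = analyze_trials(((m, streams[m["trial_id"]]) for m in trial_rows),
                            config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv",
                       index=name == "confusion")
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["log"], fh, indent=2)
    return bundle
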