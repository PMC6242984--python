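"""Per-trial attention measures and their by-items aggregation.

Four measures per face region, computed from the retained fixations of a
trial: probability of first fixation (after discarding the carried-over
central fixation), probability of entry with entry time, net gaze
duration, and number of fixations.  Region membership of a fixation is
decided by its centroid (per-sample attribution is available for gaze
duration).  Item norms average the per-trial measures across
participants for each stimulus, which is the unit of analysis of the
downstream statistics.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import SAMPLE_FIXATION, Segmentation
from .geometry import (
    ROI_LABELS,
    RegionOfInterest,
    ScreenGeometry,
    assign_roi_batch,
    degrees_per_pixel,
)

__all__ = [
    "first_fixation_roi",
    "entry_stats",
    "gaze_durations",
    "fixation_counts",
    "coverage",
    "trial_metrics",
    "aggregate_by_items",
]


def _center_radius_px(screen: ScreenGeometry, radius_deg: float) -> float:
    dppx, dppy = degrees_per_pixel(screen)
    return radius_deg / ((dppx + dppy) / 2.0)


def _is_center(fix: pd.DataFrame, center_px: tuple[float, float],
               radius_px: float) -> np.ndarray:
    return (np.hypot(fix["x_px"].to_numpy() - center_px[0],
                     fix["y_px"].to_numpy() - center_px[1]) <= radius_px)


def _drop_leading_center(fix: pd.DataFrame, center_px: tuple[float, float],
                         radius_px: float) -> pd.DataFrame:
    """Drop the carried-over central fixation(s) at the start of a trial.

    Only *leading* fixations whose centroid lies within the centre
    radius are removed; a later return to the same location is a genuine
    nose fixation and is kept.
    """
    if not len(fix):
        return fix
    center = _is_center(fix, center_px, radius_px)
    k = 0
    while k < len(fix) and center[k]:
        k += 1
    return fix.iloc[k:]


def first_fixation_roi(
    fixations: pd.DataFrame,
    center_px: tuple[float, float],
    screen: ScreenGeometry,
    center_radius_deg: float = 1.0,
) -> str:
    """Region of the first fixation after leaving the central location.

    Every leading fixation whose centroid lies within
    ``center_radius_deg`` of ``center_px`` is treated as the carried-over
    pre-stimulus fixation and skipped; the label of the next retained
    fixation is returned, or ``"none"`` when the gaze never left the
    centre.
    """
    radius = _center_radius_px(screen, center_radius_deg)
    rest = _drop_leading_center(fixations, center_px, radius)
    if not len(rest):
        return "none"
    return str(rest.iloc[0]["roi"])


def entry_stats(
    fixations: pd.DataFrame,
    center_px: tuple[float, float],
    screen: ScreenGeometry,
    center_radius_deg: float = 1.0,
    roi_labels: Sequence[str] = ROI_LABELS,
    exclude_initial_center: bool = True,
) -> tuple[dict[str, bool], dict[str, float]]:
    """Whether and when each region was entered during the trial.

    A region is entered iff at least one retained fixation (after the
    carried-over central fixation, when ``exclude_initial_center``) lies
    in it; the entry time is the onset of the earliest such fixation
    (NaN when never entered).
    """
    fix = fixations
    if exclude_initial_center:
        fix = _drop_leading_center(fix, center_px,
                                   _center_radius_px(screen, center_radius_deg))
    entered = {}
    entry_time = {}
    for label in roi_labels:
        sub = fix[fix["roi"] == label]
        entered[label] = bool(len(sub))
        entry_time[label] = float(sub["onset_ms"].iloc[0]) if len(sub) else math.nan
    return entered, entry_time


def gaze_durations(
    segmentation: Segmentation,
    stream: pd.DataFrame | None = None,
    rois: Sequence[RegionOfInterest] | None = None,
    roi_labels: Sequence[str] = ROI_LABELS,
    per_sample: bool = False,
) -> dict[str, float]:
    """Net gaze duration (ms) per region, plus ``"other"``.

    By default every net-gaze sample inherits the region of its owning
    fixation's centroid, keeping durations consistent with fixation
    counts.  With ``per_sample=True`` each sample is attributed by its
    own position instead (``stream`` and ``rois`` required).
    """
    out = {label: 0.0 for label in (*roi_labels, "other")}
    fix = segmentation.fixations
    mask = segmentation.labels == SAMPLE_FIXATION
    if per_sample:
        if stream is None or rois is None:
            raise ValueError("per-sample attribution needs stream and rois")
        labels = assign_roi_batch(stream["x_px"].to_numpy()[mask],
                                  stream["y_px"].to_numpy()[mask], rois)
        for label, count in zip(*np.unique(labels, return_counts=True)):
            out[str(label)] = float(count) * segmentation.dt_ms
        return out
    for _, row in fix.iterrows():
        label = row["roi"] if row["roi"] in out else "other"
        out[label] += float(row["duration_ms"])
    return out


def fixation_counts(
    fixations: pd.DataFrame,
    roi_labels: Sequence[str] = ROI_LABELS,
) -> dict[str, int]:
    """Number of retained fixations per region (centroid attribution)."""
    out = {label: 0 for label in (*roi_labels, "other")}
    for label in fixations["roi"]:
        out[label if label in out else "other"] += 1
    return out


def coverage(gaze_ms: Mapping[str, float],
             roi_labels: Sequence[str] = ROI_LABELS) -> float:
    """Fraction of net gaze falling inside the labelled regions.

    NaN when the trial has no net gaze at all.
    """
    total = float(sum(gaze_ms.values()))
    if total <= 0:
        return math.nan
    return sum(float(gaze_ms[label]) for label in roi_labels) / total


def trial_metrics(
    segmentation: Segmentation,
    center_px: tuple[float, float],
    screen: ScreenGeometry,
    center_radius_deg: float = 1.0,
    roi_labels: Sequence[str] = ROI_LABELS,
) -> dict[str, object]:
    """All four measures for one segmented trial, as a flat record.

    The fixation table of ``segmentation`` must already carry region
    labels (pass ``rois`` to the detector).
    """
    fix = segmentation.fixations
    first = first_fixation_roi(fix, center_px, screen, center_radius_deg)
    entered, entry_time = entry_stats(fix, center_px, screen, center_radius_deg,
                                      roi_labels)
    gaze = gaze_durations(segmentation, roi_labels=roi_labels)
    counts = fixation_counts(fix, roi_labels)
    budget = segmentation.time_budget()
    rec: dict[str, object] = {"first_fix_roi": first}
    for label in roi_labels:
        rec[f"entered_{label}"] = entered[label]
        rec[f"entry_{label}_ms"] = entry_time[label]
    for label in (*roi_labels, "other"):
        rec[f"gaze_{label}_ms"] = gaze[label]
        rec[f"nfix_{label}"] = counts[label]
    rec["coverage"] = coverage(gaze, roi_labels)
    rec["saccade_ms"] = budget["saccade"]
    rec["invalid_ms"] = budget["invalid"]
    rec["discarded_ms"] = budget["discarded"]
    rec["total_ms"] = float(len(segmentation.labels) * segmentation.dt_ms)
    return rec


def aggregate_by_items(
    trial_table: pd.DataFrame,
    roi_labels: Sequence[str] = ROI_LABELS,
) -> pd.DataFrame:
    """By-items norms: per-stimulus means (and SDs) across participants.

    ``trial_table`` holds one row per trial with at least ``stimulus_id``,
    ``expression`` and the :func:`trial_metrics` columns.  First-fixation
    probabilities are shares of trials per label among trials with a
    defined (non-``"none"``) first fixation; entry times average over
    entrant trials only.  Sample SDs use ``ddof=1``.
    """
    rows = []
    for stim, grp in trial_table.groupby("stimulus_id", sort=True):
        if not len(grp):                       # pragma: no cover - defensive
            warnings.warn(f"stimulus {stim} has no trials; excluded")
            continue
        rec: dict[str, object] = {
            "stimulus_id": stim,
            "expression": grp["expression"].iloc[0],
            "n_trials": len(grp),
        }
        defined = grp[grp["first_fix_roi"] != "none"]
        denom = len(defined)
        for label in (*roi_labels, "other"):
            rec[f"p_first_{label}"] = (
                float((defined["first_fix_roi"] == label).sum() / denom)
                if denom else math.nan)
        for label in roi_labels:
            rec[f"p_entry_{label}"] = float(grp[f"entered_{label}"].mean())
            times = grp.loc[grp[f"entered_{label}"], f"entry_{label}_ms"]
            rec[f"entry_{label}_ms"] = float(times.mean()) if len(times) else math.nan
            rec[f"entry_{label}_ms_sd"] = (float(times.std(ddof=1))
                                           if len(times) > 1 else math.nan)
        for label in roi_labels:
            for measure in (f"gaze_{label}_ms", f"nfix_{label}"):
                rec[measure] = float(grp[measure].mean())
                rec[f"{measure}_sd"] = (float(grp[measure].std(ddof=1))
                                        if len(grp) > 1 else math.nan)
        rec["coverage"] = float(grp["coverage"].mean())
        rows.append(rec)
    return pd.DataFrame(rows)
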