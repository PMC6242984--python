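"""Gaze time-course: 100-ms binning and attentional-advantage profiles.

Net gaze is split into ten consecutive 100-ms intervals across the
display (the trailing remainder of a 1,033-ms clip — its final ~33 ms —
is excluded).  For each face region the proportion of each bin spent in
net gaze on that region is computed per trial and averaged by items.
An expression holds an *advantage* on a region in a bin when its mean
proportion exceeds, and differs significantly from (omnibus ANOVA
gate, then Bonferroni pairwise contrasts), every expression in the
comparison set.  The *threshold* is the earliest such bin and the
*amplitude* the number of consecutive advantage bins from it.

The proportion denominator is the bin length, not the fixated time in
the bin, so saccade/blink time dilutes all regions equally and the
regional proportions of a bin sum to at most 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import SAMPLE_FIXATION, Segmentation
from .geometry import EXPRESSIONS, ROI_LABELS
from .stats import bonferroni_pairwise, oneway_anova

__all__ = [
    "AdvantageProfile",
    "bin_gaze_proportions",
    "timecourse_by_items",
    "advantage_profile",
    "advantage_report",
]


@dataclass(frozen=True)
class AdvantageProfile:
    """Threshold/amplitude of one expression's advantage on one region.

    ``threshold_bin`` is the earliest 1-based bin with an advantage
    (None when no bin qualifies), ``amplitude_bins`` the length of the
    consecutive advantage run starting there, and ``advantage_bins``
    every qualifying bin, consecutive or not.
    """

    expression: str
    roi: str
    threshold_bin: int | None
    amplitude_bins: int
    advantage_bins: tuple[int, ...]
    comparison_set: tuple[str, ...]


def bin_gaze_proportions(
    segmentation: Segmentation,
    bin_ms: float = 100.0,
    n_bins: int = 10,
    roi_labels: Sequence[str] = ROI_LABELS,
) -> pd.DataFrame:
    """Per-bin net-gaze proportions of one trial.

    Returns rows ``(roi, bin, proportion)`` for each region and
    ``"other"``, bins numbered 1..n_bins.  Each net-gaze sample is
    attributed to the bin containing it and to its owning fixation's
    region; the proportion is regional net time in the bin divided by
    the bin length.  Trials shorter than ``n_bins * bin_ms`` are
    rejected.
    """
    n = len(segmentation.labels)
    duration = n * segmentation.dt_ms
    if duration < n_bins * bin_ms:
        raise ValueError(f"trial covers only {duration:.0f} ms, "
                         f"need {n_bins * bin_ms:.0f} for binning")
    t = np.arange(n) * segmentation.dt_ms
    mask = segmentation.labels == SAMPLE_FIXATION
    bins = (t / bin_ms).astype(int)
    fix = segmentation.fixations
    roi_of_fix = fix["roi"].to_numpy() if len(fix) else np.empty(0, dtype=object)

    labels_all = (*roi_labels, "other")
    acc = {(label, b): 0.0 for label in labels_all for b in range(n_bins)}
    owners = segmentation.owner
    for i in np.flatnonzero(mask):
        b = bins[i]
        if b >= n_bins:
            continue
        label = roi_of_fix[owners[i]]
        if label not in roi_labels:
            label = "other"
        acc[(label, b)] += segmentation.dt_ms
    rows = [(label, b + 1, acc[(label, b)] / bin_ms)
            for label in labels_all for b in range(n_bins)]
    return pd.DataFrame(rows, columns=["roi", "bin", "proportion"])


def timecourse_by_items(trial_bins: pd.DataFrame) -> pd.DataFrame:
    """Average per-trial bin proportions into a by-items table.

    ``trial_bins`` needs columns ``stimulus_id``, ``expression``,
    ``roi``, ``bin``, ``proportion`` (one row per trial x region x bin);
    the result holds their mean across trials for each stimulus.
    """
    out = (trial_bins
           .groupby(["stimulus_id", "expression", "roi", "bin"], sort=True)
           ["proportion"].mean().reset_index())
    return out


def advantage_profile(
    items: pd.DataFrame,
    expression: str,
    roi: str,
    comparison_set: Sequence[str] | None = None,
    alpha: float = 0.05,
    n_bins: int = 10,
) -> AdvantageProfile:
    """Threshold and amplitude of an expression's regional advantage.

    ``items`` is a by-items table (see :func:`timecourse_by_items`).
    Per bin, a one-way by-items ANOVA across all expressions present
    gates Bonferroni pairwise contrasts pooled on its error term; the
    expression holds the advantage when its mean exceeds and differs
    significantly from every member of ``comparison_set`` (all other
    expressions by default — pass a subset to probe partial advantages,
    e.g. excluding a co-leading expression).
    """
    comparison = tuple(comparison_set) if comparison_set is not None else tuple(
        e for e in items["expression"].unique() if e != expression)
    if not comparison:
        raise ValueError("comparison_set must name at least one expression")
    if expression in comparison:
        raise ValueError("an expression cannot be compared with itself")
    sub = items[items["roi"] == roi]
    advantage = []
    for b in range(1, n_bins + 1):
        binned = sub[sub["bin"] == b]
        groups = {e: binned.loc[binned["expression"] == e, "proportion"].to_numpy()
                  for e in binned["expression"].unique()}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"need >= 2 items per expression in bin {b}")
        omnibus = oneway_anova(groups)
        if not omnibus.p < alpha:
            continue
        contrasts = bonferroni_pairwise(groups, omnibus.ms_error,
                                        omnibus.df_error, alpha)
        mean_e = groups[expression].mean()
        if all(mean_e > groups[c].mean() and contrasts.significant(expression, c)
               for c in comparison):
            advantage.append(b)
    if not advantage:
        return AdvantageProfile(expression, roi, None, 0, (), comparison)
    threshold = advantage[0]
    amplitude = 1
    while threshold + amplitude in advantage:
        amplitude += 1
    return AdvantageProfile(expression, roi, threshold, amplitude,
                            tuple(advantage), comparison)


def advantage_report(
    items: pd.DataFrame,
    alpha: float = 0.05,
    n_bins: int = 10,
    expressions: Sequence[str] = EXPRESSIONS,
    roi_labels: Sequence[str] = ROI_LABELS,
) -> pd.DataFrame:
    """Advantage profiles for every expression x region pair."""
    rows = []
    present = [e for e in expressions if e in set(items["expression"])]
    for roi in roi_labels:
        for e in present:
            prof = advantage_profile(items, e, roi,
                                     [x for x in present if x != e],
                                     alpha, n_bins)
            rows.append({
                "expression": e,
                "roi": roi,
                "threshold_bin": prof.threshold_bin,
                "amplitude_bins": prof.amplitude_bins,
                "advantage_bins": ",".join(map(str, prof.advantage_bins)),
                "comparison_set": ",".join(prof.comparison_set),
            })
    return pd.DataFrame(rows)
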