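"""Velocity-threshold (I-VT) event detection on gaze sample streams.

A gaze stream is a per-trial table of timestamped positions with a
validity flag (columns ``t_ms``, ``x_px``, ``y_px``, ``valid``).  Samples
are classified by instantaneous angular speed: runs at or above the peak
velocity threshold are saccades, runs below it are fixation candidates,
and candidates shorter than the minimum fixation duration are discarded.
Invalid samples (eye not tracked) break runs; maximal invalid runs at or
above a minimum duration are blinks, shorter ones are dropouts.  Either
way invalid time never counts toward net gaze.

Durations are counted on the sample grid: a sample at time ``t`` owns the
interval ``[t, t + dt)`` with ``dt`` the nominal sampling interval, so a
run of ``k`` samples lasts ``k * dt`` ms.  At the 500-Hz default a 40-
sample run is exactly the 80-ms minimum fixation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import RegionOfInterest, ScreenGeometry, assign_roi_batch, degrees_per_pixel

__all__ = [
    "sample_velocity",
    "detect_fixations_ivt",
    "detect_blinks",
    "net_gaze_mask",
    "Segmentation",
    "SAMPLE_FIXATION",
    "SAMPLE_SACCADE",
    "SAMPLE_DISCARDED",
    "SAMPLE_INVALID",
]

# per-sample classification codes
SAMPLE_FIXATION = 0   # member of a retained (>= min duration) fixation
SAMPLE_SACCADE = 1    # at/above the velocity threshold
SAMPLE_DISCARDED = 2  # fixation candidate below the minimum duration
SAMPLE_INVALID = 3    # eye not tracked (blink or dropout)

GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "valid")


@dataclass
class Segmentation:
    """Result of I-VT segmentation of one trial.

    Attributes
    ----------
    events
        One row per fixation/saccade event: ``kind`` (``"fixation"`` or
        ``"saccade"``), ``onset_ms``, ``offset_ms``, ``duration_ms``,
        ``x_px``/``y_px`` (fixation centroid, NaN for saccades), ``roi``
        (when regions were supplied) and ``n_samples``.
    labels
        Per-sample classification code (``SAMPLE_*`` above).
    owner
        Per-sample index into the fixation rows of ``events`` (-1 where
        the sample belongs to no retained fixation).
    dt_ms
        Nominal sampling interval.
    """

    events: pd.DataFrame
    labels: np.ndarray
    owner: np.ndarray
    dt_ms: float

    @property
    def fixations(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "fixation"].reset_index(drop=True)

    def time_budget(self) -> dict[str, float]:
        """Per-class sample time in ms; sums to n_samples * dt exactly."""
        names = {SAMPLE_FIXATION: "fixation", SAMPLE_SACCADE: "saccade",
                 SAMPLE_DISCARDED: "discarded", SAMPLE_INVALID: "invalid"}
        return {name: float(np.sum(self.labels == code) * self.dt_ms)
                for code, name in names.items()}


def _as_arrays(stream: pd.DataFrame) -> tuple[np.ndarray, ...]:
    t = np.asarray(stream["t_ms"], dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("gaze timestamps must be strictly increasing")
    x = np.asarray(stream["x_px"], dtype=float)
    y = np.asarray(stream["y_px"], dtype=float)
    valid = np.asarray(stream["valid"], dtype=bool)
    return t, x, y, valid


def sample_velocity(stream: pd.DataFrame, screen: ScreenGeometry) -> np.ndarray:
    """Instantaneous angular speed (deg/s) at each sample.

    Central difference over the two neighbours where both are valid;
    one-sided difference at the stream ends or next to invalid samples;
    NaN where no valid neighbour exists or the sample itself is invalid.
    Angular distance uses the per-axis small-angle pixel subtense.
    """
    t, x, y, valid = _as_arrays(stream)
    n = len(t)
    if n < 2:
        return np.full(n, np.nan)
    dppx, dppy = degrees_per_pixel(screen)
    xd = x * dppx
    yd = y * dppy

    v = np.full(n, np.nan)
    idx = np.arange(n)
    prev_ok = np.zeros(n, dtype=bool)
    next_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = valid[:-1]
    next_ok[:-1] = valid[1:]

    def speed(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        dist = np.hypot(xd[j] - xd[i], yd[j] - yd[i])
        return dist / (t[j] - t[i]) * 1000.0

    central = valid & prev_ok & next_ok
    ci = idx[central]
    v[ci] = speed(ci - 1, ci + 1)
    fwd = valid & ~prev_ok & next_ok
    fi = idx[fwd]
    v[fi] = speed(fi, fi + 1)
    bwd = valid & prev_ok & ~next_ok
    bi = idx[bwd]
    v[bi] = speed(bi - 1, bi)
    return v


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal state as (state, start, stop) with stop exclusive."""
    out = []
    n = len(states)
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        out.append((int(states[i]), i, j))
        i = j
    return out


def _nominal_dt(t: np.ndarray) -> float:
    if len(t) < 2:
        return 2.0
    return float(np.median(np.diff(t)))


def detect_fixations_ivt(
    stream: pd.DataFrame,
    screen: ScreenGeometry,
    velocity_threshold: float = 40.0,
    min_fixation_ms: float = 80.0,
    rois: Sequence[RegionOfInterest] | None = None,
    smoothing_window: int | None = None,
) -> Segmentation:
    """Segment one trial into fixations and saccades by velocity.

    Samples with speed >= ``velocity_threshold`` (deg/s) form saccades;
    below-threshold runs form fixation candidates; candidates shorter
    than ``min_fixation_ms`` are discarded (their time is excluded from
    net gaze but still accounted for).  Valid samples whose speed is
    undefined (isolated between invalid neighbours) are treated as
    stationary.  ``smoothing_window``, when given, applies a centred
    moving average of that many samples to the speed trace first.
    An empty or all-invalid stream yields an empty event table.
    """
    t, x, y, valid = _as_arrays(stream)
    n = len(t)
    dt = _nominal_dt(t)
    if n == 0:
        events = pd.DataFrame(columns=["kind", "onset_ms", "offset_ms",
                                       "duration_ms", "x_px", "y_px", "roi",
                                       "n_samples"])
        return Segmentation(events, np.empty(0, dtype=int), np.empty(0, dtype=int), dt)

    v = sample_velocity(stream, screen)
    if smoothing_window and smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        finite = np.where(np.isfinite(v), v, 0.0)
        weight = np.convolve(np.isfinite(v).astype(float), kernel, mode="same")
        smoothed = np.convolve(finite, kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(weight > 0, smoothed / weight, np.nan)

    # provisional per-sample state; undefined speed counts as stationary
    state = np.full(n, SAMPLE_DISCARDED)
    state[~valid] = SAMPLE_INVALID
    fast = valid & np.isfinite(v) & (v >= velocity_threshold)
    state[fast] = SAMPLE_SACCADE

    labels = state.copy()
    owner = np.full(n, -1)
    rows = []
    fix_idx = 0
    for st, i, j in _runs(state):
        if st == SAMPLE_INVALID:
            continue
        onset = t[i]
        duration = (j - i) * dt
        if st == SAMPLE_SACCADE:
            rows.append(("saccade", onset, onset + duration, duration,
                         np.nan, np.nan, "", j - i))
        else:
            if duration >= min_fixation_ms:
                labels[i:j] = SAMPLE_FIXATION
                owner[i:j] = fix_idx
                fix_idx += 1
                rows.append(("fixation", onset, onset + duration, duration,
                             float(np.mean(x[i:j])), float(np.mean(y[i:j])),
                             "", j - i))
            # short candidates keep the SAMPLE_DISCARDED label, no event row
    events = pd.DataFrame(rows, columns=["kind", "onset_ms", "offset_ms",
                                         "duration_ms", "x_px", "y_px", "roi",
                                         "n_samples"])
    if rois is not None and len(events):
        is_fix = events["kind"] == "fixation"
        if is_fix.any():
            events.loc[is_fix, "roi"] = assign_roi_batch(
                events.loc[is_fix, "x_px"].to_numpy(),
                events.loc[is_fix, "y_px"].to_numpy(), rois)
    return Segmentation(events, labels, owner, dt)


def detect_blinks(stream: pd.DataFrame, min_blink_ms: float = 75.0) -> pd.DataFrame:
    """Maximal invalid runs of at least ``min_blink_ms`` as blink intervals.

    Shorter invalid runs are tracking dropouts; both are excluded from
    net gaze, the distinction is purely descriptive.  Returns a table
    with ``kind`` (``"blink"``/``"dropout"``), onset, offset, duration.
    """
    t, _, _, valid = _as_arrays(stream)
    dt = _nominal_dt(t)
    rows = []
    for st, i, j in _runs((~valid).astype(int)):
        if st != 1:
            continue
        duration = (j - i) * dt
        kind = "blink" if duration >= min_blink_ms else "dropout"
        rows.append((kind, t[i], t[i] + duration, duration))
    return pd.DataFrame(rows, columns=["kind", "onset_ms", "offset_ms",
                                       "duration_ms"])


def net_gaze_mask(stream: pd.DataFrame, segmentation: Segmentation) -> np.ndarray:
    """Boolean per-sample mask of net gaze.

    True exactly where the sample belongs to a retained fixation; saccade,
    blink/dropout and discarded-candidate samples are False.  Together
    with :meth:`Segmentation.time_budget` this satisfies the conservation
    identity: fixation + saccade + invalid + discarded time equals the
    stream's sampled duration.
    """
    if len(stream) != len(segmentation.labels):
        raise ValueError("segmentation does not match the stream length")
    return segmentation.labels == SAMPLE_FIXATION
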