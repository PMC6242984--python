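"""Synthetic gaze-scanpath and categorization-response generator.

Emulates per-trial raw data of a dynamic facial-expression experiment:
500-Hz gaze samples over a ~1-s clip, starting on a central fixation
location on the nose (carried over from the pre-stimulus fixation
cross), then alternating fixation plateaus on face regions and
constant-velocity saccade ramps, with optional blink dropouts.  Region
targeting follows an expression-specific attention profile: the first
post-centre saccade target is drawn from a first-target bias, and
subsequent targets from (possibly time-varying) dwell weights.
Categorization responses are drawn from a row-stochastic confusion
model with log-normal reaction times measured from clip offset.

The generator is the test bed of the analysis pipeline, not a model of
oculomotor physiology: saccades are straight constant-velocity ramps
above the detection threshold rather than main-sequence profiles, and
fixation noise is clipped so that plateau sample-to-sample velocity
stays below the threshold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    EXPRESSIONS,
    ROI_LABELS,
    RegionOfInterest,
    ScreenGeometry,
    StimulusEntry,
    build_default_rois,
    default_face_box,
    default_screen,
    degrees_per_pixel,
)

__all__ = [
    "AttentionProfile",
    "SimulationConfig",
    "ConfusionModel",
    "SimulatedTrial",
    "simulate_trial",
    "simulate_response",
    "simulate_experiment",
    "iter_experiment",
    "default_profiles",
    "default_setup",
]

TARGET_LABELS = ROI_LABELS + ("other",)


@dataclass(frozen=True)
class AttentionProfile:
    """Expression-conditioned region-targeting parameters.

    ``dwell_weights`` maps each target label (eyes, nose, mouth, other)
    to either a single nonnegative weight or a sequence of weights, one
    per 100-ms segment of the display, allowing attention to shift over
    time.  Weights are normalised per segment when targets are drawn.
    ``first_target_bias`` gives the probability that the first saccade
    away from the centre lands in each region.
    """

    expression: str
    dwell_weights: Mapping[str, float | Sequence[float]]
    first_target_bias: Mapping[str, float]

    def __post_init__(self) -> None:
        bias = np.array([self.first_target_bias.get(k, 0.0) for k in TARGET_LABELS])
        if bias.min() < 0 or not np.isclose(bias.sum(), 1.0, atol=1e-6):
            raise ValueError("first_target_bias must be a probability "
                             "vector over eyes/nose/mouth/other")
        n_seg = self.n_segments
        for seg in range(n_seg):
            if sum(self._weight(k, seg) for k in TARGET_LABELS) <= 0:
                raise ValueError(f"dwell weights sum to zero in segment {seg}")
            if any(self._weight(k, seg) < 0 for k in TARGET_LABELS):
                raise ValueError("dwell weights must be nonnegative")

    @property
    def n_segments(self) -> int:
        return max((len(w) for w in self.dwell_weights.values()
                    if isinstance(w, Sequence) and not isinstance(w, str)),
                   default=1)

    def _weight(self, label: str, segment: int) -> float:
        w = self.dwell_weights.get(label, 0.0)
        if isinstance(w, Sequence) and not isinstance(w, str):
            return float(w[min(segment, len(w) - 1)])
        return float(w)

    def weights_at(self, t_ms: float, segment_ms: float = 100.0) -> np.ndarray:
        """Normalised target probabilities in effect at time ``t_ms``."""
        seg = int(t_ms // segment_ms)
        w = np.array([self._weight(k, seg) for k in TARGET_LABELS])
        return w / w.sum()

    def mean_weights(self, n_segments: int = 10) -> dict[str, float]:
        """Time-averaged normalised dwell weights over the display."""
        acc = np.zeros(len(TARGET_LABELS))
        for seg in range(n_segments):
            acc += self.weights_at(seg * 100.0)
        acc /= n_segments
        return dict(zip(TARGET_LABELS, acc))


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and statistical parameters of the trial generator.

    Defaults mirror the recording conditions the analysis defaults
    assume: 500-Hz sampling of a 1,033-ms display with gaze starting on
    the nose.  ``fixation_duration_lognorm`` is ``(median_ms, sigma)`` of
    the log-normal fixation-duration distribution (median 250 ms, a
    conventional empirical value); durations are clipped to
    ``fixation_duration_clip_ms``.  ``center_hold_ms`` bounds the
    residual duration of the carried-over central fixation.  Positional
    noise is Gaussian with ``positional_noise_deg`` SD, hard-clipped at
    ``positional_noise_clip_deg`` per axis so that plateau velocity can
    never reach the 40 deg/s detection threshold at 500 Hz.
    """

    sampling_rate_hz: float = 500.0
    trial_duration_ms: float = 1033.0
    fixation_duration_lognorm: tuple[float, float] = (250.0, 0.4)
    fixation_duration_clip_ms: tuple[float, float] = (60.0, 800.0)
    center_hold_ms: tuple[float, float] = (150.0, 450.0)
    saccade_peak_velocity_deg_s: float = 300.0
    min_saccade_amplitude_deg: float = 0.5
    blink_rate_per_trial: float = 0.2
    blink_duration_lognorm: tuple[float, float] = (150.0, 0.3)
    blink_duration_clip_ms: tuple[float, float] = (80.0, 300.0)
    positional_noise_deg: float = 0.015
    positional_noise_clip_deg: float = 0.05
    center_start_px: tuple[float, float] = (840.0, 525.0)
    segment_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.trial_duration_ms <= 0:
            raise ValueError("rate and duration must be positive")
        if self.saccade_peak_velocity_deg_s <= 40.0:
            raise ValueError("saccade velocity must exceed the 40 deg/s "
                             "detection threshold")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return int(np.ceil(self.trial_duration_ms / self.dt_ms))


@dataclass(frozen=True)
class ConfusionModel:
    """Row-stochastic stimulus-by-response categorization model.

    ``matrix[i, j]`` is the probability of responding ``labels[j]`` to a
    stimulus of ``labels[i]``.  Reaction times (from clip offset) are
    log-normal with per-expression median ``rt_location_ms`` and spread
    ``rt_scale_ms`` (the log-sigma is ``scale/location``).
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    rt_location_ms: Mapping[str, float]
    rt_scale_ms: Mapping[str, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix shape does not match labels")
        if m.min() < 0 or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must sum to 1")
        for lab in self.labels:
            if self.rt_location_ms[lab] <= 0 or self.rt_scale_ms[lab] < 0:
                raise ValueError("RT parameters must be positive")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, labels: Sequence[str] = EXPRESSIONS,
                 rt_location_ms: float = 1000.0,
                 rt_scale_ms: float = 150.0) -> "ConfusionModel":
        n = len(labels)
        return cls(tuple(labels), np.eye(n),
                   {l: rt_location_ms for l in labels},
                   {l: rt_scale_ms for l in labels})

    @classmethod
    def uniform(cls, labels: Sequence[str] = EXPRESSIONS,
                rt_location_ms: float = 1000.0,
                rt_scale_ms: float = 150.0) -> "ConfusionModel":
        n = len(labels)
        return cls(tuple(labels), np.full((n, n), 1.0 / n),
                   {l: rt_location_ms for l in labels},
                   {l: rt_scale_ms for l in labels})


@dataclass
class SimulatedTrial:
    """One generated trial: the raw stream plus its ground truth."""

    stream: pd.DataFrame
    segments: pd.DataFrame   # kind, roi, start_ms, end_ms (programmed truth)
    blinks: pd.DataFrame     # start_ms, end_ms


# ---------------------------------------------------------------------------
# default study conditions

# Expression-specific dwell weights over eyes / nose-cheek / mouth / other.
# They encode the qualitative attention pattern the pipeline is meant to
# detect: eyes-dominant angry and sad faces, nose/cheek-dominant disgust,
# a mouth advantage for happiness, intermediate balanced profiles for
# surprise and fear, and ~3% of dwell outside the three regions (matching
# the ~97% regional coverage typical of face viewing).  Within each
# region the six values are pairwise separated by at least 0.02 so the
# programmed cross-expression ordering is statistically recoverable.
_DEFAULT_DWELL: dict[str, dict[str, float]] = {
    "happiness": {"eyes": 0.27, "nose": 0.37, "mouth": 0.33, "other": 0.03},
    "surprise":  {"eyes": 0.40, "nose": 0.28, "mouth": 0.29, "other": 0.03},
    "anger":     {"eyes": 0.51, "nose": 0.33, "mouth": 0.13, "other": 0.03},
    "sadness":   {"eyes": 0.48, "nose": 0.31, "mouth": 0.18, "other": 0.03},
    "disgust":   {"eyes": 0.35, "nose": 0.42, "mouth": 0.20, "other": 0.03},
    "fear":      {"eyes": 0.44, "nose": 0.26, "mouth": 0.27, "other": 0.03},
}

# First post-centre saccade target probabilities, from the published
# normative first-fixation shares for dynamic expressions (eyes-biased
# everywhere, with a mouth boost for happiness); the remainder to 1 is
# the off-region share.
_DEFAULT_FIRST_BIAS: dict[str, dict[str, float]] = {
    "happiness": {"eyes": 0.478, "nose": 0.231, "mouth": 0.236, "other": 0.055},
    "surprise":  {"eyes": 0.533, "nose": 0.218, "mouth": 0.189, "other": 0.060},
    "anger":     {"eyes": 0.548, "nose": 0.229, "mouth": 0.154, "other": 0.069},
    "sadness":   {"eyes": 0.542, "nose": 0.240, "mouth": 0.156, "other": 0.062},
    "disgust":   {"eyes": 0.516, "nose": 0.245, "mouth": 0.168, "other": 0.071},
    "fear":      {"eyes": 0.512, "nose": 0.230, "mouth": 0.193, "other": 0.065},
}


def default_profiles() -> dict[str, AttentionProfile]:
    """The six default expression attention profiles."""
    return {e: AttentionProfile(e, _DEFAULT_DWELL[e], _DEFAULT_FIRST_BIAS[e])
            for e in EXPRESSIONS}


def default_setup() -> tuple[ScreenGeometry, tuple[float, float, float, float],
                             tuple[RegionOfInterest, ...], SimulationConfig]:
    """Screen, face box, default regions and simulation config."""
    screen = default_screen()
    face_box = default_face_box(screen)
    rois = build_default_rois(face_box)
    return screen, face_box, rois, SimulationConfig()


# ---------------------------------------------------------------------------
# trial generation

def _sample_point_in(rng: np.random.Generator, roi: RegionOfInterest,
                     avoid: tuple[float, float] | None,
                     min_dist_px: float) -> tuple[float, float]:
    minx, miny, maxx, maxy = roi.polygon.bounds
    for _ in range(200):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not roi.contains(x, y):
            continue
        if avoid is not None and np.hypot(x - avoid[0], y - avoid[1]) < min_dist_px:
            continue
        return x, y
    return (minx + maxx) / 2.0, (miny + maxy) / 2.0


def _sample_point_other(rng: np.random.Generator,
                        face_box: tuple[float, float, float, float],
                        rois: Sequence[RegionOfInterest],
                        avoid: tuple[float, float] | None,
                        min_dist_px: float) -> tuple[float, float]:
    x0, y0, w, h = face_box
    for _ in range(200):
        x = rng.uniform(x0, x0 + w)
        y = rng.uniform(y0, y0 + h)
        if any(r.contains(x, y) for r in rois):
            continue
        if avoid is not None and np.hypot(x - avoid[0], y - avoid[1]) < min_dist_px:
            continue
        return x, y
    return x0 + w / 2.0, y0 + 0.05 * h  # forehead fallback


def _lognormal(rng: np.random.Generator, median: float, sigma: float,
               clip: tuple[float, float]) -> float:
    return float(np.clip(rng.lognormal(np.log(median), sigma), *clip))


def simulate_trial(
    profile: AttentionProfile,
    config: SimulationConfig,
    rois: Sequence[RegionOfInterest],
    screen: ScreenGeometry,
    rng: np.random.Generator | int,
    face_box: tuple[float, float, float, float] | None = None,
) -> SimulatedTrial:
    """Generate one trial's gaze stream.

    The stream starts at ``config.center_start_px`` (the carried-over
    central fixation), holds there for a residual duration, then
    alternates saccades and fixations until the display ends.  The first
    saccade target is drawn from the profile's first-target bias, later
    targets from its dwell weights in effect at fixation onset.  Blink
    intervals overwrite samples as invalid with blank coordinates.
    Identical ``rng`` seed gives a bitwise-identical stream.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not rois:
        raise ValueError("at least one region of interest is required")
    face_box = face_box or default_face_box(screen)
    by_label = {r.label: r for r in rois}
    dppx, dppy = degrees_per_pixel(screen)
    px_per_deg = 1.0 / dppx
    dt = config.dt_ms
    n = config.n_samples
    duration = n * dt

    def draw_target(kind: str, cur: tuple[float, float]) -> tuple[float, float]:
        min_dist = config.min_saccade_amplitude_deg * px_per_deg
        if kind == "other":
            return _sample_point_other(rng, face_box, rois, cur, min_dist)
        return _sample_point_in(rng, by_label[kind], cur, min_dist)

    # --- build the programmed event schedule in continuous time
    segments: list[tuple[str, str, float, float, tuple[float, float],
                         tuple[float, float]]] = []
    cur_t = 0.0
    cur_pos = config.center_start_px
    hold = rng.uniform(*config.center_hold_ms)
    segments.append(("fixation", "center", cur_t, min(cur_t + hold, duration),
                     cur_pos, cur_pos))
    cur_t += hold
    first = True
    bias = np.array([profile.first_target_bias.get(k, 0.0) for k in TARGET_LABELS])
    bias = bias / bias.sum()
    while cur_t < duration:
        if first:
            label = rng.choice(TARGET_LABELS, p=bias)
            first = False
        else:
            label = rng.choice(TARGET_LABELS,
                               p=profile.weights_at(cur_t, config.segment_ms))
        target = draw_target(label, cur_pos)
        dist_deg = np.hypot((target[0] - cur_pos[0]) * dppx,
                            (target[1] - cur_pos[1]) * dppy)
        sacc_ms = max(dist_deg / config.saccade_peak_velocity_deg_s * 1000.0, dt)
        segments.append(("saccade", "", cur_t, min(cur_t + sacc_ms, duration),
                         cur_pos, target))
        cur_t += sacc_ms
        if cur_t >= duration:
            break
        fix_ms = _lognormal(rng, *config.fixation_duration_lognorm,
                            config.fixation_duration_clip_ms)
        segments.append(("fixation", label, cur_t, min(cur_t + fix_ms, duration),
                         target, target))
        cur_t += fix_ms
        cur_pos = target

    # --- rasterise onto the sample grid
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    clip = config.positional_noise_clip_deg
    for kind, _label, start, end, p0, p1 in segments:
        i0 = int(np.ceil(start / dt - 1e-9))
        i1 = min(int(np.ceil(end / dt - 1e-9)), n)
        if i1 <= i0:
            continue
        if kind == "fixation":
            noise = rng.normal(0.0, config.positional_noise_deg, (i1 - i0, 2))
            noise = np.clip(noise, -clip, clip)
            x[i0:i1] = p0[0] + noise[:, 0] / dppx
            y[i0:i1] = p0[1] + noise[:, 1] / dppy
        else:
            frac = (t[i0:i1] - start) / (end - start)
            x[i0:i1] = p0[0] + frac * (p1[0] - p0[0])
            y[i0:i1] = p0[1] + frac * (p1[1] - p0[1])

    # --- blinks: runs of invalid samples with blank coordinates
    valid = np.ones(n, dtype=bool)
    blink_rows = []
    for _ in range(rng.poisson(config.blink_rate_per_trial)):
        b_ms = _lognormal(rng, *config.blink_duration_lognorm,
                          config.blink_duration_clip_ms)
        b_start = rng.uniform(0.0, max(duration - b_ms, 0.0))
        i0 = int(np.ceil(b_start / dt - 1e-9))
        i1 = min(i0 + int(round(b_ms / dt)), n)
        valid[i0:i1] = False
        blink_rows.append((t[i0], t[min(i1, n - 1)] + dt))
    x[~valid] = np.nan
    y[~valid] = np.nan

    stream = pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y, "valid": valid})
    seg_df = pd.DataFrame(
        [(k, lab, s, e) for k, lab, s, e, _p0, _p1 in segments],
        columns=["kind", "roi", "start_ms", "end_ms"])
    blink_df = pd.DataFrame(blink_rows, columns=["start_ms", "end_ms"])
    return SimulatedTrial(stream, seg_df, blink_df)


def simulate_response(
    model: ConfusionModel,
    expression: str,
    rng: np.random.Generator | int,
) -> tuple[str, float]:
    """Draw a categorization response and its RT for one stimulus."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    row = model.matrix[model.labels.index(expression)]
    response = str(rng.choice(model.labels, p=row))
    loc = model.rt_location_ms[expression]
    sigma = model.rt_scale_ms[expression] / loc
    rt = float(rng.lognormal(np.log(loc), sigma))
    return response, rt


def iter_experiment(
    n_participants: int,
    registry: Sequence[StimulusEntry],
    profiles: Mapping[str, AttentionProfile],
    confusion_model: ConfusionModel,
    config: SimulationConfig,
    rois: Sequence[RegionOfInterest],
    screen: ScreenGeometry,
    seed: int,
    block_size: int = 40,
    face_box: tuple[float, float, float, float] | None = None,
) -> Iterator[tuple[dict, SimulatedTrial]]:
    """Lazily yield ``(trial_metadata, simulated_trial)`` pairs.

    Every participant sees every registry entry exactly once, in an
    order randomised per participant; trials are grouped into blocks of
    ``block_size``.  Per-trial generators are seeded from
    ``(seed, participant, trial_index)`` so any single trial is
    reproducible without generating the ones before it.
    """
    missing = {e.expression for e in registry} - set(profiles)
    if missing:
        raise ValueError(f"no attention profile for expressions: {sorted(missing)}")
    for p in range(n_participants):
        order = np.random.default_rng([seed, p]).permutation(len(registry))
        for idx, stim_i in enumerate(order):
            entry = registry[stim_i]
            trial_rng = np.random.default_rng([seed, p, idx])
            trial = simulate_trial(profiles[entry.expression], config, rois,
                                   screen, trial_rng, face_box)
            response, rt = simulate_response(confusion_model, entry.expression,
                                             trial_rng)
            meta = {
                "participant": p + 1,
                "trial_index": idx + 1,
                "block": idx // block_size + 1,
                "trial_id": f"p{p + 1:03d}_t{idx + 1:03d}",
                "stimulus_id": entry.stimulus_id,
                "model_id": entry.model_id,
                "expression": entry.expression,
                "response": response,
                "rt_ms": rt,
                "correct": int(response == entry.expression),
            }
            yield meta, trial


def simulate_experiment(
    n_participants: int,
    registry: Sequence[StimulusEntry],
    profiles: Mapping[str, AttentionProfile],
    confusion_model: ConfusionModel,
    config: SimulationConfig,
    rois: Sequence[RegionOfInterest],
    screen: ScreenGeometry,
    seed: int,
    block_size: int = 40,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a whole experiment into in-memory tables.

    Returns ``(gaze, trials)``: the concatenated gaze streams (with a
    ``trial_id`` column) and the trial metadata table.  For large runs
    prefer :func:`iter_experiment` and process trials one at a time.
    """
    streams = []
    metas = []
    for meta, trial in iter_experiment(n_participants, registry, profiles,
                                       confusion_model, config, rois, screen,
                                       seed, block_size):
        s = trial.stream.copy()
        s.insert(0, "trial_id", meta["trial_id"])
        streams.append(s)
        metas.append(meta)
    gaze = pd.concat(streams, ignore_index=True) if streams else pd.DataFrame(
        columns=["trial_id", "t_ms", "x_px", "y_px", "valid"])
    return gaze, pd.DataFrame(metas)
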