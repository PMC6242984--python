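"""File formats, run configuration and the shipped normative fixture.

All interchange formats are delimited text: gaze streams and trial
metadata as CSV/TSV (dialect auto-detected on read, written as comma),
run configuration as JSON.  Missing gaze is encoded as ``valid = 0``
with blank coordinates, never as sentinel positions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .categorization import ConfusionMatrix
from .geometry import (
    EXPRESSIONS,
    RegionOfInterest,
    ScreenGeometry,
    build_default_rois,
    default_face_box,
    default_screen,
)
from .simulate import ConfusionModel

__all__ = [
    "GAZE_HEADER",
    "read_gaze_file",
    "write_gaze_file",
    "read_trials_file",
    "write_trials_file",
    "RunConfig",
    "load_categorization_norms",
    "norms_confusion_model",
]

GAZE_HEADER = ("trial_id", "t_ms", "x_px", "y_px", "valid")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def write_gaze_file(gaze: pd.DataFrame, path: str | Path) -> None:
    """Write a multi-trial gaze table; invalid samples get blank coordinates."""
    out = gaze[list(GAZE_HEADER)].copy()
    out["valid"] = out["valid"].astype(int)
    invalid = out["valid"] == 0
    out["x_px"] = out["x_px"].astype(object)
    out["y_px"] = out["y_px"].astype(object)
    out.loc[invalid, ["x_px", "y_px"]] = ""
    out.to_csv(path, index=False)


def read_gaze_file(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read per-trial gaze streams from a delimited-text file.

    Returns an ordered mapping trial_id -> stream (``t_ms``, ``x_px``,
    ``y_px``, ``valid``).  Malformed rows raise with their line number;
    non-monotone timestamps raise naming the trial.  An empty file with
    a valid header yields no trials.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    streams: dict[str, dict[str, list]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header "
                             f"{','.join(GAZE_HEADER)}") from None
        if tuple(h.strip() for h in header) != GAZE_HEADER:
            raise ValueError(f"{path}: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, "
                                 f"got {len(row)}")
            trial, t_s, x_s, y_s, valid_s = (c.strip() for c in row)
            try:
                t = float(t_s)
                valid = int(valid_s)
                if valid not in (0, 1):
                    raise ValueError
                x = float(x_s) if x_s else np.nan
                y = float(y_s) if y_s else np.nan
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from None
            if valid == 1 and (np.isnan(x) or np.isnan(y)):
                raise ValueError(f"{path}:{lineno}: valid sample without "
                                 "coordinates")
            s = streams.setdefault(trial, {"t_ms": [], "x_px": [], "y_px": [],
                                           "valid": []})
            s["t_ms"].append(t)
            s["x_px"].append(x)
            s["y_px"].append(y)
            s["valid"].append(bool(valid))
    out = {}
    for trial, cols in streams.items():
        df = pd.DataFrame(cols)
        dt = np.diff(df["t_ms"].to_numpy())
        if len(dt) and np.any(dt <= 0):
            raise ValueError(f"{path}: non-monotone timestamps in trial "
                             f"{trial!r}")
        out[trial] = df
    return out


def write_trials_file(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials_file(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    required = {"trial_id", "stimulus_id", "expression"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"{path}: trial table missing columns {sorted(missing)}")
    return trials


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Validated parameter set shared by every pipeline stage.

    Detection defaults are the standard velocity-based settings (40 deg/s
    peak velocity, 80-ms minimum fixation), binning defaults the ten
    100-ms intervals, alpha the 0.05 familywise threshold.
    """

    screen: ScreenGeometry = field(default_factory=default_screen)
    face_box: tuple[float, float, float, float] | None = None
    roi_vertices: Mapping[str, list[tuple[float, float]]] | None = None
    velocity_threshold: float = 40.0
    min_fixation_ms: float = 80.0
    min_blink_ms: float = 75.0
    smoothing_window: int | None = None
    bin_ms: float = 100.0
    n_bins: int = 10
    alpha: float = 0.05
    center_px: tuple[float, float] | None = None
    center_radius_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.min_fixation_ms <= 0:
            raise ValueError("detection parameters must be positive")
        if self.min_blink_ms < 0 or self.bin_ms <= 0 or self.n_bins < 1:
            raise ValueError("binning/blink parameters out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def resolve_face_box(self) -> tuple[float, float, float, float]:
        return self.face_box or default_face_box(self.screen)

    def resolve_rois(self) -> tuple[RegionOfInterest, ...]:
        if self.roi_vertices is not None:
            return tuple(RegionOfInterest(label, tuple(map(tuple, verts)))
                         for label, verts in self.roi_vertices.items())
        return build_default_rois(self.resolve_face_box())

    def resolve_center(self) -> tuple[float, float]:
        if self.center_px is not None:
            return tuple(self.center_px)
        return (self.screen.width_px / 2.0, self.screen.height_px / 2.0)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["screen"] = asdict(self.screen)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        d["screen"] = ScreenGeometry(**d["screen"])
        if d.get("face_box") is not None:
            d["face_box"] = tuple(d["face_box"])
        if d.get("center_px") is not None:
            d["center_px"] = tuple(d["center_px"])
        return cls(**d)


# ---------------------------------------------------------------------------
# shipped normative fixture

def load_categorization_norms() -> tuple[ConfusionMatrix, pd.DataFrame, pd.DataFrame]:
    """Published by-items categorization norms for the six expressions.

    Returns ``(matrix, confusions, rts)``: the mean stimulus-by-response
    confusion matrix (proportions; rows renormalised from the printed
    percentages), the long-format table of printed means and SDs in
    percent, and the correct-response RT means/SDs in ms.  The loader
    validates the packaged data: six-by-six layout, printed rows summing
    to ~100%, and RTs for every expression — a mismatch means a broken
    installation.
    """
    pkg = resources.files("facegaze").joinpath("data")
    with resources.as_file(pkg.joinpath("confusion_norms.csv")) as p:
        conf = pd.read_csv(p)
    with resources.as_file(pkg.joinpath("hit_rt_norms.csv")) as p:
        rts = pd.read_csv(p)
    wide = conf.pivot(index="stimulus", columns="response", values="mean_pct")
    try:
        wide = wide.loc[list(EXPRESSIONS), list(EXPRESSIONS)]
    except KeyError as exc:
        raise RuntimeError("categorization norms fixture is incomplete") from exc
    sums = wide.to_numpy().sum(axis=1)
    if np.any(np.abs(sums - 100.0) > 1.5) or set(rts["expression"]) != set(EXPRESSIONS):
        raise RuntimeError("categorization norms fixture failed validation")
    props = wide.to_numpy() / wide.to_numpy().sum(axis=1, keepdims=True)
    matrix = ConfusionMatrix(EXPRESSIONS, props, tuple([40] * 6))
    return matrix, conf, rts


def norms_confusion_model() -> ConfusionModel:
    """The shipped norms as a generative response model."""
    matrix, _conf, rts = load_categorization_norms()
    rt_loc = dict(zip(rts["expression"], rts["rt_mean_ms"].astype(float)))
    rt_scale = dict(zip(rts["expression"], rts["rt_sd_ms"].astype(float)))
    return ConfusionModel(EXPRESSIONS, matrix.proportions, rt_loc, rt_scale)
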