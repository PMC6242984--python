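import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import facegaze as fg

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture(scope="session")
def screen():
    return fg.default_screen()


@pytest.fixture(scope="session")
def face_box(screen):
    return fg.default_face_box(screen)


@pytest.fixture(scope="session")
def rois(face_box):
    return fg.build_default_rois(face_box)


@pytest.fixture(scope="session")
def sim_setup():
    return fg.default_setup()


def make_stream(segments, dt=2.0, t0=0.0):
    """Build a gaze stream from (kind, duration_ms, ...) plateau/ramp specs.

    segments: list of tuples —
      ("hold", duration_ms, (x, y))           stationary plateau
      ("ramp", duration_ms, (x0, y0), (x1, y1)) linear motion
      ("gap", duration_ms)                     invalid samples
    """
    t, x, y, valid = [], [], [], []
    cur = t0
    for seg in segments:
        kind, dur = seg[0], seg[1]
        n = int(round(dur / dt))
        for i in range(n):
            t.append(cur + i * dt)
            if kind == "hold":
                x.append(seg[2][0]); y.append(seg[2][1]); valid.append(True)
            elif kind == "ramp":
                f = i / n
                x.append(seg[2][0] + f * (seg[3][0] - seg[2][0]))
                y.append(seg[2][1] + f * (seg[3][1] - seg[2][1]))
                valid.append(True)
            elif kind == "gap":
                x.append(math.nan); y.append(math.nan); valid.append(False)
            else:
                raise ValueError(kind)
        cur += n * dt
    return pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y, "valid": valid})


# ---------------------------------------------------------------------------
# independent brute-force oracles used across test modules

def oracle_velocity(stream, screen):
    """Per-sample angular speed by explicit per-sample recomputation."""
    dppx, dppy = fg.degrees_per_pixel(screen)
    t = stream["t_ms"].to_list()
    x = stream["x_px"].to_list()
    y = stream["y_px"].to_list()
    valid = stream["valid"].to_list()
    n = len(t)
    out = [math.nan] * n
    for i in range(n):
        if not valid[i]:
            continue
        prev_ok = i > 0 and valid[i - 1]
        next_ok = i < n - 1 and valid[i + 1]
        if prev_ok and next_ok:
            a, b = i - 1, i + 1
        elif next_ok:
            a, b = i, i + 1
        elif prev_ok:
            a, b = i - 1, i
        else:
            continue
        dist = math.hypot((x[b] - x[a]) * dppx, (y[b] - y[a]) * dppy)
        out[i] = dist / (t[b] - t[a]) * 1000.0
    return out


def oracle_segment(stream, screen, threshold=40.0, min_fix_ms=80.0, dt=2.0):
    """Exhaustive run-length I-VT segmentation; returns per-sample labels.

    Labels: 'fix', 'sacc', 'disc', 'inval' — the same partition the
    detector encodes numerically.
    """
    v = oracle_velocity(stream, screen)
    valid = stream["valid"].to_list()
    n = len(valid)
    state = []
    for i in range(n):
        if not valid[i]:
            state.append("inval")
        elif not math.isnan(v[i]) and v[i] >= threshold:
            state.append("sacc")
        else:
            state.append("cand")
    labels = list(state)
    i = 0
    while i < n:
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        if state[i] == "cand":
            name = "fix" if (j - i) * dt >= min_fix_ms else "disc"
            for k in range(i, j):
                labels[k] = name
        i = j
    return labels


CODE_TO_NAME = {0: "fix", 1: "sacc", 2: "disc", 3: "inval"}


def random_stream(rng, n=120, dt=2.0, screen=None):
    """A random gaze stream mixing drift, jumps and invalid runs."""
    screen = screen or fg.default_screen()
    x = [800.0]
    y = [500.0]
    for _ in range(n - 1):
        if rng.random() < 0.08:      # saccade-like jump
            x.append(x[-1] + rng.normal(0, 60))
            y.append(y[-1] + rng.normal(0, 60))
        else:
            x.append(x[-1] + rng.normal(0, 0.4))
            y.append(y[-1] + rng.normal(0, 0.4))
    valid = np.ones(n, dtype=bool)
    for _ in range(rng.integers(0, 3)):
        start = rng.integers(0, n)
        length = rng.integers(1, 60)
        valid[start:start + length] = False
    x = np.array(x); y = np.array(y)
    x[~valid] = np.nan
    y[~valid] = np.nan
    return pd.DataFrame({"t_ms": np.arange(n) * dt, "x_px": x, "y_px": y,
                         "valid": valid})
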