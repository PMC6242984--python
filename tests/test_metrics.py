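import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import facegaze as fg

from conftest import make_stream

CENTER = (840.0, 525.0)


def fix_df(rows):
    """fixation table from (onset, duration, x, y, roi) tuples"""
    return pd.DataFrame(
        [{"kind": "fixation", "onset_ms": on, "offset_ms": on + dur,
          "duration_ms": dur, "x_px": x, "y_px": y, "roi": roi,
          "n_samples": int(dur // 2)} for on, dur, x, y, roi in rows],
        columns=["kind", "onset_ms", "offset_ms", "duration_ms", "x_px",
                 "y_px", "roi", "n_samples"])


@pytest.fixture(scope="module")
def batch():
    """2,000 simulated trials under the default happiness profile.

    Centre hold is disabled so every fixation is driven by the
    programmed profile; blinks are off for exact time accounting of the
    recovery checks (conservation with blinks is covered elsewhere).
    """
    screen, _fb, rois, cfg = fg.default_setup()
    cfg = replace(cfg, center_hold_ms=(0.0, 0.0), blink_rate_per_trial=0.0)
    prof = fg.default_profiles()["happiness"]
    rows = []
    for seed in range(2000):
        trial = fg.simulate_trial(prof, cfg, rois, screen, seed)
        seg = fg.detect_fixations_ivt(trial.stream, screen, rois=rois)
        rows.append(fg.trial_metrics(seg, cfg.center_start_px, screen))
    return pd.DataFrame(rows), prof


class TestFirstFixation:
    def test_center_then_mouth(self, screen):
        fix = fix_df([(0, 250, 840, 525, "nose"),
                      (280, 220, 770, 720, "mouth")])
        assert fg.first_fixation_roi(fix, CENTER, screen) == "mouth"

    def test_only_center_gives_none(self, screen):
        fix = fix_df([(0, 900, 841, 526, "nose")])
        assert fg.first_fixation_roi(fix, CENTER, screen) == "none"

    def test_later_return_to_center_counts(self, screen):
        # a non-leading fixation near the centre is a genuine nose fixation
        fix = fix_df([(0, 250, 840, 525, "nose"),
                      (300, 200, 750, 420, "eyes"),
                      (550, 200, 842, 523, "nose")])
        assert fg.first_fixation_roi(fix, CENTER, screen) == "eyes"
        entered, times = fg.entry_stats(fix, CENTER, screen)
        assert entered["nose"] and times["nose"] == 550

    def test_bias_recovery(self, batch):
        # programmed first-target shares recovered within +-0.04
        table, prof = batch
        defined = table[table["first_fix_roi"] != "none"]
        for roi in fg.ROI_LABELS:
            share = (defined["first_fix_roi"] == roi).mean()
            assert share == pytest.approx(prof.first_target_bias[roi],
                                          abs=0.04)


class TestEntry:
    def test_single_mouth_fixation(self, screen):
        fix = fix_df([(0, 250, 840, 525, "nose"),
                      (320, 200, 770, 720, "mouth")])
        entered, times = fg.entry_stats(fix, CENTER, screen)
        assert entered["mouth"] and times["mouth"] == 320
        assert not entered["eyes"] and math.isnan(times["eyes"])

    def test_entry_dominates_first_fixation(self, batch):
        table, _ = batch
        defined = table[table["first_fix_roi"] != "none"]
        for roi in fg.ROI_LABELS:
            p_first = (defined["first_fix_roi"] == roi).mean()
            p_entry = table[f"entered_{roi}"].mean()
            assert p_entry >= p_first


class TestGazeDurations:
    def test_single_eyes_fixation_exact(self, screen, rois):
        eyes = next(r for r in rois if r.label == "eyes").polygon.centroid
        stream = make_stream([("gap", 20), ("hold", 300, (eyes.x, eyes.y)),
                              ("gap", 20)])
        seg = fg.detect_fixations_ivt(stream, screen, rois=rois)
        gaze = fg.gaze_durations(seg)
        assert gaze["eyes"] == pytest.approx(300.0)
        assert sum(v for k, v in gaze.items() if k != "eyes") == 0.0

    def test_conservation_identity(self, batch):
        table, _ = batch
        gaze_cols = [f"gaze_{l}_ms" for l in (*fg.ROI_LABELS, "other")]
        total = (table[gaze_cols].sum(axis=1) + table["saccade_ms"]
                 + table["invalid_ms"] + table["discarded_ms"])
        assert np.allclose(total, table["total_ms"])

    def test_per_sample_attribution_option(self, screen, rois):
        eyes = next(r for r in rois if r.label == "eyes").polygon.centroid
        stream = make_stream([("gap", 20), ("hold", 300, (eyes.x, eyes.y)),
                              ("gap", 20)])
        seg = fg.detect_fixations_ivt(stream, screen, rois=rois)
        per_sample = fg.gaze_durations(seg, stream=stream, rois=rois,
                                       per_sample=True)
        assert per_sample["eyes"] == pytest.approx(300.0, abs=4.0)


class TestFixationCounts:
    def test_boundary_inclusive_counting(self):
        fix = fix_df([(0, 80, 750, 420, "eyes"),
                      (100, 120, 751, 421, "eyes"),
                      (240, 300, 752, 419, "eyes")])
        assert fg.fixation_counts(fix)["eyes"] == 3

    def test_min_duration_bounds_gaze(self, batch):
        table, _ = batch
        for roi in fg.ROI_LABELS:
            assert (table[f"gaze_{roi}_ms"]
                    >= 80.0 * table[f"nfix_{roi}"] - 1e-9).all()

    def test_empty(self):
        assert fg.fixation_counts(fix_df([])) == {
            "eyes": 0, "nose": 0, "mouth": 0, "other": 0}


class TestCoverage:
    def test_constructed_values(self):
        assert fg.coverage({"eyes": 300, "nose": 200, "mouth": 100,
                            "other": 0}) == 1.0
        assert fg.coverage({"eyes": 300, "nose": 0, "mouth": 0,
                            "other": 300}) == 0.5
        assert math.isnan(fg.coverage({"eyes": 0, "nose": 0, "mouth": 0,
                                       "other": 0}))

    def test_programmed_off_region_share(self, batch):
        # 3% "other" dwell weight -> mean coverage ~= 0.97
        table, _ = batch
        assert table["coverage"].mean() == pytest.approx(0.97, abs=0.01)


class TestAggregateByItems:
    def test_mean_and_sample_sd(self):
        rows = []
        for p, gaze in ((1, 100.0), (2, 200.0)):
            rows.append({"stimulus_id": "M01_fear", "expression": "fear",
                         "participant": p, "first_fix_roi": "eyes",
                         "entered_eyes": True, "entry_eyes_ms": 300.0,
                         "entered_nose": False, "entry_nose_ms": math.nan,
                         "entered_mouth": False, "entry_mouth_ms": math.nan,
                         "gaze_eyes_ms": gaze, "nfix_eyes": 1,
                         "gaze_nose_ms": 0.0, "nfix_nose": 0,
                         "gaze_mouth_ms": 0.0, "nfix_mouth": 0,
                         "gaze_other_ms": 0.0, "nfix_other": 0,
                         "coverage": 1.0})
        norms = fg.aggregate_by_items(pd.DataFrame(rows))
        assert len(norms) == 1
        assert norms.loc[0, "gaze_eyes_ms"] == 150.0
        assert norms.loc[0, "gaze_eyes_ms_sd"] == pytest.approx(70.7107, abs=1e-3)
        assert norms.loc[0, "p_first_eyes"] == 1.0
        assert norms.loc[0, "p_entry_eyes"] == 1.0

    def test_identical_trials_zero_sd(self):
        rows = [{"stimulus_id": "s", "expression": "anger",
                 "first_fix_roi": "nose", "entered_eyes": False,
                 "entry_eyes_ms": math.nan, "entered_nose": True,
                 "entry_nose_ms": 100.0, "entered_mouth": False,
                 "entry_mouth_ms": math.nan, "gaze_eyes_ms": 0.0,
                 "nfix_eyes": 0, "gaze_nose_ms": 400.0, "nfix_nose": 2,
                 "gaze_mouth_ms": 0.0, "nfix_mouth": 0, "gaze_other_ms": 0.0,
                 "nfix_other": 0, "coverage": 1.0}] * 3
        norms = fg.aggregate_by_items(pd.DataFrame(rows))
        assert norms.loc[0, "gaze_nose_ms_sd"] == 0.0
        assert norms.loc[0, "n_trials"] == 3

    def test_entry_time_over_entrants_only(self):
        rows = []
        for entered, t in ((True, 200.0), (True, 400.0), (False, math.nan)):
            rows.append({"stimulus_id": "s", "expression": "fear",
                         "first_fix_roi": "eyes", "entered_eyes": entered,
                         "entry_eyes_ms": t, "entered_nose": False,
                         "entry_nose_ms": math.nan, "entered_mouth": False,
                         "entry_mouth_ms": math.nan, "gaze_eyes_ms": 0.0,
                         "nfix_eyes": 0, "gaze_nose_ms": 0.0, "nfix_nose": 0,
                         "gaze_mouth_ms": 0.0, "nfix_mouth": 0,
                         "gaze_other_ms": 0.0, "nfix_other": 0,
                         "coverage": 1.0})
        norms = fg.aggregate_by_items(pd.DataFrame(rows))
        assert norms.loc[0, "entry_eyes_ms"] == 300.0
        assert norms.loc[0, "p_entry_eyes"] == pytest.approx(2 / 3)
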