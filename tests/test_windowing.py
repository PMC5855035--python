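"""Active/transition segmentation: hit-testing, the 500 ms validity rule
and the deletion-then-join behavior."""

import numpy as np
import pandas as pd
import pytest

from cogload.session import AoI
from cogload.simulate import SimulationConfig, simulate_session
from cogload.windowing import (MIN_WINDOW_MS, Window, label_samples,
                               merge_after_deletion, segment_windows,
                               session_windows)

LAYOUT = (AoI("news1", (0, 0, 100, 100)), AoI("ad1", (200, 0, 300, 100)))


def gaze_frame(rows):
    """rows: (t, x, y, event)"""
    return pd.DataFrame({
        "t": [r[0] for r in rows],
        "x": [r[1] for r in rows],
        "y": [r[2] for r in rows],
        "event": [r[3] for r in rows],
    })


class TestLabelSamples:
    def test_fixation_at_aoi_centroid_is_active(self):
        g = gaze_frame([(0, 50.0, 50.0, "fixation")])
        out = label_samples(g, LAYOUT)
        assert out.loc[0, "state"] == "active"
        assert out.loc[0, "aoi"] == "news1"

    def test_fixation_outside_every_aoi_is_transition(self):
        g = gaze_frame([(0, 150.0, 50.0, "fixation")])
        assert label_samples(g, LAYOUT).loc[0, "state"] == "transition"

    def test_missing_coordinates_are_inactive(self):
        g = gaze_frame([(0, np.nan, np.nan, "blink")])
        assert label_samples(g, LAYOUT).loc[0, "state"] == "inactive"

    def test_saccade_inside_aoi_counts_as_transition(self):
        # hit-testing applies to fixations only
        g = gaze_frame([(0, 50.0, 50.0, "saccade")])
        assert label_samples(g, LAYOUT).loc[0, "state"] == "transition"

    def test_half_open_rectangle_edges(self):
        g = gaze_frame([(0, 0.0, 0.0, "fixation"), (8, 100.0, 50.0, "fixation")])
        out = label_samples(g, LAYOUT)
        assert out.loc[0, "state"] == "active"      # min edge included
        assert out.loc[1, "state"] == "transition"  # max edge excluded


def run(state, aoi, t0, t1):
    return {"state": state, "aoi": aoi, "t_start": float(t0), "t_end": float(t1)}


def states_from_runs(runs, period=10.0):
    rows = []
    for r in runs:
        for t in np.arange(r["t_start"], r["t_end"], period):
            rows.append({"t": t, "state": r["state"], "aoi": r["aoi"]})
    return pd.DataFrame(rows)


class TestMergeAfterDeletion:
    def test_same_aoi_joined_across_deleted_transition(self):
        runs = [run("active", "a", 0, 600), run("transition", "", 600, 800),
                run("active", "a", 800, 1500)]
        out = merge_after_deletion(runs)
        assert out == [Window("active", 0, 1500, "a")]

    def test_sub_threshold_pieces_merge_into_valid_window(self):
        runs = [run("active", "a", 0, 300), run("transition", "", 300, 500),
                run("active", "a", 500, 800)]
        out = merge_after_deletion(runs)
        assert out == [Window("active", 0, 800, "a")]

    def test_different_aois_do_not_merge(self):
        runs = [run("active", "a", 0, 600), run("transition", "", 600, 700),
                run("active", "b", 700, 1300)]
        out = merge_after_deletion(runs)
        assert [w.aoi_id for w in out] == ["a", "b"]

    def test_transitions_merge_like_active_windows(self):
        runs = [run("transition", "", 0, 300), run("active", "x", 300, 550),
                run("transition", "", 550, 850)]
        out = merge_after_deletion(runs)
        assert out == [Window("transition", 0, 850, "")]

    def test_inner_stitch_beats_outer_bridge(self):
        # a valid active window made of short fixations must not be swallowed
        # by the surrounding transition
        runs = [run("transition", "", 0, 700),
                run("active", "a", 700, 1000), run("transition", "", 1000, 1040),
                run("active", "a", 1040, 1400),
                run("transition", "", 1400, 2100)]
        out = merge_after_deletion(runs)
        assert out == [Window("transition", 0, 700, ""),
                       Window("active", 700, 1400, "a"),
                       Window("transition", 1400, 2100, "")]

    def test_long_inactive_run_is_a_barrier(self):
        runs = [run("active", "a", 0, 600), run("inactive", "", 600, 1600),
                run("active", "a", 1600, 2200)]
        out = merge_after_deletion(runs)
        assert len(out) == 2
        assert all(w.kind == "active" for w in out)

    def test_short_blink_gap_is_bridged(self):
        runs = [run("active", "a", 0, 600), run("inactive", "", 600, 800),
                run("active", "a", 800, 1400)]
        out = merge_after_deletion(runs)
        assert out == [Window("active", 0, 1400, "a")]


class TestSegmentWindows:
    def test_three_valid_runs_yield_three_windows(self):
        states = states_from_runs([
            run("active", "a", 0, 600), run("transition", "", 600, 1150),
            run("active", "b", 1150, 1950)])
        out = segment_windows(states)
        assert [(w.kind, w.aoi_id) for w in out] == [
            ("active", "a"), ("transition", ""), ("active", "b")]

    def test_single_run_just_below_threshold_deleted(self):
        states = states_from_runs([run("active", "a", 0, 490)], period=10.0)
        assert segment_windows(states) == []

    def test_threshold_is_strict_at_499_vs_500(self):
        assert merge_after_deletion([run("active", "a", 0, 499)]) == []
        assert merge_after_deletion([run("active", "a", 0, 500)]) == [
            Window("active", 0, 500, "a")]

    def test_emitted_windows_at_least_500_ms(self):
        states = states_from_runs([
            run("active", "a", 0, 450), run("transition", "", 450, 900),
            run("active", "b", 900, 1200)])
        for w in segment_windows(states):
            assert w.duration_ms >= MIN_WINDOW_MS

    def test_idempotent_on_clean_sequences(self):
        states = states_from_runs([
            run("active", "a", 0, 800), run("transition", "", 800, 1600),
            run("active", "b", 1600, 2400)])
        first = segment_windows(states)
        again = segment_windows(states)
        assert first == again


class TestOnSimulatedSessions:
    def test_windows_ordered_nonoverlapping_and_valid(self, small_session):
        s, _ = small_session
        ws = session_windows(s)
        assert len(ws) > 3
        for a, b in zip(ws, ws[1:]):
            assert a.t_end <= b.t_start
        assert all(w.duration_ms >= MIN_WINDOW_MS for w in ws)

    def test_boundary_recovery_within_one_sample(self):
        cfg = SimulationConfig(seed=5, session_duration_s=120.0, channels=(),
                               blink_rate_hz=0.0)
        s, truth = simulate_session(cfg, 0)
        ws = session_windows(s)
        period = 1000.0 / cfg.gaze_rate_hz
        tol = period + 0.51  # rasterized to integer milliseconds
        hits = 0
        for r in truth.windows.itertuples():
            if any(w.kind == r.kind
                   and abs(w.t_start - r.t_start) <= tol
                   and abs(w.t_end - r.t_end) <= tol for w in ws):
                hits += 1
        assert hits / len(truth.windows) >= 0.95
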