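"""Sleep architecture: bout calling vs a run-length oracle, the
sleep+wake partition, wake-gated locomotion speed, the light-response and
rebound ratios, and the deprivation schedule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from larvasleep.activity import BehaviorTrace, CentroidTrack
from larvasleep.errors import InvalidParameterError
from larvasleep.sleep import (
    call_sleep_bouts, deprivation_schedule, light_response_index,
    locomotion_speed, rebound_index, sleep_metrics, sleep_seconds_in_interval,
)
from larvasleep.synthetic import simulate_behavior_trace

from conftest import maximal_inactive_runs_oracle

FPS = 0.87


def _trace(states, fps=FPS):
    return BehaviorTrace(np.array(states, dtype=bool), fps=fps)


class TestBoutCalling:
    def test_twelve_frame_run_is_one_bout(self):
        trace = _trace([1] * 5 + [0] * 12 + [1] * 5)
        bouts = call_sleep_bouts(trace)
        assert [(b.start_frame, b.end_frame) for b in bouts] == [(5, 17)]
        assert bouts[0].n_frames == 12

    def test_eleven_frame_run_is_wake(self):
        trace = _trace([1] * 5 + [0] * 11 + [1] * 5)
        assert call_sleep_bouts(trace) == []

    def test_all_active_empty(self):
        assert call_sleep_bouts(_trace([1] * 50)) == []

    def test_edge_bouts_count_if_long_enough(self):
        trace = _trace([0] * 12 + [1] * 3 + [0] * 15)
        assert [(b.start_frame, b.end_frame) for b in call_sleep_bouts(trace)] \
            == [(0, 12), (15, 30)]

    @given(st.lists(st.booleans(), min_size=1, max_size=120),
           st.integers(min_value=1, max_value=15))
    def test_matches_run_length_oracle(self, states, min_frames):
        bouts = call_sleep_bouts(_trace(states), min_frames=min_frames)
        expected = [(s, e) for s, e in maximal_inactive_runs_oracle(states)
                    if e - s >= min_frames]
        assert [(b.start_frame, b.end_frame) for b in bouts] == expected

    def test_many_random_traces_vs_oracle(self, rng):
        for _ in range(2000):
            states = rng.random(rng.integers(12, 80)) > 0.5
            bouts = call_sleep_bouts(_trace(states), min_frames=5)
            expected = [(s, e) for s, e in maximal_inactive_runs_oracle(states)
                        if e - s >= 5]
            assert [(b.start_frame, b.end_frame) for b in bouts] == expected

    @given(st.lists(st.booleans(), min_size=30, max_size=120))
    def test_threshold_monotonicity(self, states):
        trace = _trace(states)
        totals = [sum(b.n_frames for b in call_sleep_bouts(trace, m))
                  for m in (1, 6, 12, 20)]
        assert totals == sorted(totals, reverse=True)


class TestSleepMetrics:
    def test_no_bouts(self):
        trace = _trace([1] * 100)
        m = sleep_metrics([], trace)
        assert m.total_sleep_s == 0
        assert np.isnan(m.sleep_latency_s)
        assert m.total_wake_s == pytest.approx(100 / FPS)

    def test_single_bout_duration_identity(self):
        trace = _trace([0] * 200)
        bouts = call_sleep_bouts(trace)
        m = sleep_metrics(bouts, trace)
        assert m.total_sleep_s == pytest.approx(200 / 0.87)

    def test_partition_exact(self, rng):
        """total_sleep + total_wake equals the window length exactly."""
        for _ in range(50):
            states = rng.random(300) > 0.4
            trace = _trace(states)
            bouts = call_sleep_bouts(trace, min_frames=5)
            t1 = float(rng.uniform(50, 300 / FPS))
            t0 = float(rng.uniform(0, t1 - 10))
            m = sleep_metrics(bouts, trace, window=(t0, t1))
            assert m.total_sleep_s + m.total_wake_s == pytest.approx(
                t1 - t0, abs=1e-12)

    def test_brute_force_frame_summation(self, rng):
        """Bout-window intersections agree with naive per-frame summation
        on frame-aligned windows."""
        for _ in range(20):
            states = rng.random(200) > 0.5
            trace = _trace(states, fps=1.0)  # 1 fps: frames are seconds
            bouts = call_sleep_bouts(trace, min_frames=3)
            asleep = np.zeros(200, dtype=bool)
            for b in bouts:
                asleep[b.start_frame:b.end_frame] = True
            w = (20.0, 180.0)
            m = sleep_metrics(bouts, trace, window=w)
            assert m.total_sleep_s == pytest.approx(asleep[20:180].sum())

    def test_window_outside_recording_rejected(self):
        trace = _trace([1] * 10)
        with pytest.raises(InvalidParameterError):
            sleep_metrics([], trace, window=(0, 100.0))


class TestLocomotionSpeed:
    def test_stationary_all_wake_zero(self):
        track = CentroidTrack(np.zeros((50, 2)), np.ones(50, bool))
        assert locomotion_speed(track, [], FPS) == 0.0

    def test_constant_displacement_closed_form(self):
        d = 0.25
        pos = np.column_stack([np.arange(40) * d, np.zeros(40)])
        track = CentroidTrack(pos, np.ones(40, bool))
        assert locomotion_speed(track, [], FPS) == pytest.approx(d * FPS)

    def test_invariant_to_inserted_sleep(self):
        """Inserting quiescent (stationary) stretches into a fixed wake
        trajectory leaves the wake-gated speed unchanged."""
        d = 0.3
        wake_pos = np.column_stack([np.arange(30) * d, np.zeros(30)])
        track = CentroidTrack(wake_pos, np.ones(30, bool))
        base = locomotion_speed(track, [], fps=1.0)

        pos2 = np.concatenate([wake_pos[:15],
                               np.repeat(wake_pos[14:15], 20, axis=0),
                               wake_pos[15:]])
        states = np.ones(len(pos2), dtype=bool)
        states[15:35] = False
        trace = _trace(states, fps=1.0)
        bouts = call_sleep_bouts(trace, min_frames=12)
        track2 = CentroidTrack(pos2, np.ones(len(pos2), bool))
        assert locomotion_speed(track2, bouts, fps=1.0) == pytest.approx(base)

    def test_zero_wake_returns_nan_with_warning(self):
        trace = _trace([0] * 30, fps=1.0)
        bouts = call_sleep_bouts(trace)
        track = CentroidTrack(np.zeros((30, 2)), np.ones(30, bool))
        with pytest.warns(RuntimeWarning):
            assert np.isnan(locomotion_speed(track, bouts, fps=1.0))

    def test_recovers_programmed_speed_independent_of_sleep_fraction(self):
        """Rendered videos: recovered wake speed matches the programmed
        crawl speed within 10% whether the larva sleeps little or half the
        time."""
        from larvasleep.activity import track_centroids
        from larvasleep.synthetic import MotionParams, render_larva_video
        m = MotionParams(noise_sd=0)
        speeds = []
        for mean_sleep in (15.0, 60.0):
            _, truth = simulate_behavior_trace(0.87, 1000, 60, mean_sleep, seed=4)
            stack = render_larva_video(truth, m, 96, seed=5)
            track = track_centroids(stack)
            trace = BehaviorTrace(truth.state_sequence, fps=m.fps)
            bouts = call_sleep_bouts(trace, min_frames=1)
            speeds.append(locomotion_speed(track, bouts, m.fps))
        for s in speeds:
            assert s == pytest.approx(m.crawl_speed_mean, rel=0.10)


class TestRatios:
    def test_light_response_half(self):
        assert light_response_index(1800, 3600) == 0.5

    def test_light_response_unity(self):
        assert light_response_index(1234, 1234) == 1.0

    def test_light_response_zero_baseline_undefined(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(light_response_index(100, 0))

    def test_rebound_arithmetic(self):
        assert rebound_index(600, 900) == 1.5
        assert rebound_index(700, 700) == 1.0

    def test_rebound_zero_pre_undefined(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rebound_index(0, 100))

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            light_response_index(-1, 10)
        with pytest.raises(InvalidParameterError):
            rebound_index(-1, 10)

    def test_cohort_rebound_recovery(self):
        """A cohort whose post-deprivation sleep is generated at 1.4x the
        baseline yields a median rebound index near 1.4."""
        indices = []
        for seed in range(40):
            # pre: sleep fraction 60/180 = 1/3; post: 70/150 = 0.4667 = 1.4x
            pre_tr, _ = simulate_behavior_trace(0.87, 3600, 120, 60, seed=seed)
            post_tr, _ = simulate_behavior_trace(0.87, 3600, 80, 70, seed=seed + 500)
            pre = sleep_metrics(call_sleep_bouts(pre_tr, 1), pre_tr).total_sleep_s
            post = sleep_metrics(call_sleep_bouts(post_tr, 1), post_tr).total_sleep_s
            indices.append(rebound_index(pre, post))
        assert np.median(indices) == pytest.approx(1.4, rel=0.1)


class TestDeprivationSchedule:
    def test_default_schedule(self):
        s = deprivation_schedule()
        assert s.on_intervals[0] == (3600.0, 3690.0)
        assert len(s.on_intervals) == 30
        assert s.total_on_s == 2700.0
        for a, b in s.on_intervals:
            assert b - a == 90.0

    def test_zero_session_empty(self):
        assert deprivation_schedule(session_s=0).on_intervals == []

    def test_truncated_final_interval(self):
        s = deprivation_schedule(baseline_s=100, on_s=90, off_s=30, session_s=200)
        assert s.on_intervals == [(100.0, 190.0), (220.0, 300.0)]

    def test_degenerate_cycle_rejected(self):
        with pytest.raises(InvalidParameterError):
            deprivation_schedule(on_s=0, off_s=0, session_s=10)

    def test_sleep_in_on_vs_off_intervals(self):
        trace = _trace([0] * 100, fps=1.0)
        bouts = call_sleep_bouts(trace)
        assert sleep_seconds_in_interval(bouts, (0.0, 50.0)) == 50.0
        assert sleep_seconds_in_interval(bouts, (90.0, 200.0)) == 10.0
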