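"""Generator tests: seed determinism, truth consistency, and oracle
recovery of every programmed quantity (bout structure, crawl speed, DAM
zero bins, nuclear fraction, stain fraction)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from larvasleep.errors import InvalidParameterError
from larvasleep.synthetic import (
    BodyGeometry, CellGeometry, MotionParams, inactive_runs,
    render_dyed_larva, render_larva_video, render_translocation_image,
    simulate_behavior_trace, simulate_dam_series,
)

from conftest import maximal_inactive_runs_oracle


class TestBehaviorTrace:
    def test_zero_sleep_mean_gives_all_active(self):
        trace, truth = simulate_behavior_trace(0.87, 100, 60, 0, seed=1)
        assert trace.states.all()
        assert truth.true_bouts == []

    def test_zero_wake_mean_gives_all_inactive(self):
        trace, truth = simulate_behavior_trace(0.87, 100, 0, 60, seed=1)
        assert not trace.states.any()
        assert truth.true_bouts == [(0, len(trace))]

    def test_seed_determinism(self):
        a, _ = simulate_behavior_trace(0.87, 500, 30, 45, seed=7)
        b, _ = simulate_behavior_trace(0.87, 500, 30, 45, seed=7)
        assert np.array_equal(a.states, b.states)
        c, _ = simulate_behavior_trace(0.87, 500, 30, 45, seed=8)
        assert not np.array_equal(a.states, c.states)

    @pytest.mark.parametrize("fps,dur", [(0, 10), (-1, 10), (0.87, 0)])
    def test_invalid_parameters(self, fps, dur):
        with pytest.raises(InvalidParameterError):
            simulate_behavior_trace(fps, dur, 60, 60, seed=0)

    def test_both_means_zero_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_behavior_trace(0.87, 10, 0, 0, seed=0)

    def test_pooled_inactive_fraction_matches_symmetric_means(self):
        """Equal wake/sleep means give an asymptotic inactive fraction of
        0.5; the pooled estimate over 50 seeds must sit within 3 standard
        errors (estimated across seeds, since frames within a bout are
        correlated)."""
        fracs = []
        for seed in range(50):
            trace, _ = simulate_behavior_trace(0.87, 10_000, 60, 60, seed=seed)
            fracs.append(1.0 - trace.states.mean())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_mean_bout_lengths_match_request(self):
        trace, truth = simulate_behavior_trace(0.87, 50_000, 40, 80, seed=3)
        sleep_lens = np.array([e - s for s, e in truth.true_bouts])
        assert sleep_lens.mean() / 0.87 == pytest.approx(80, rel=0.15)

    @given(st.lists(st.booleans(), min_size=0, max_size=200))
    def test_truth_bouts_equal_independent_run_length_scan(self, states):
        assert inactive_runs(np.array(states, dtype=bool)) == \
            maximal_inactive_runs_oracle(states)


class TestLarvaVideo:
    def test_all_inactive_no_noise_frames_identical(self):
        trace, truth = simulate_behavior_trace(0.87, 60, 0, 60, seed=0)
        stack = render_larva_video(truth, MotionParams(noise_sd=0), 80, seed=1)
        assert (stack.frames == stack.frames[0]).all()

    def test_all_active_no_noise_consecutive_frames_differ(self):
        trace, truth = simulate_behavior_trace(0.87, 60, 60, 0, seed=0)
        stack = render_larva_video(truth, MotionParams(noise_sd=0), 80, seed=1)
        diffs = np.abs(np.diff(stack.frames.astype(int), axis=0)).sum(axis=(1, 2))
        assert (diffs > 0).all()

    def test_seed_determinism(self):
        _, truth1 = simulate_behavior_trace(0.87, 60, 30, 30, seed=5)
        _, truth2 = simulate_behavior_trace(0.87, 60, 30, 30, seed=5)
        m = MotionParams()
        a = render_larva_video(truth1, m, 80, seed=9)
        b = render_larva_video(truth2, m, 80, seed=9)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(truth1.true_centroids, truth2.true_centroids)

    def test_larva_must_fit_in_well(self):
        _, truth = simulate_behavior_trace(0.87, 10, 30, 30, seed=0)
        with pytest.raises(InvalidParameterError):
            render_larva_video(truth, MotionParams(body_length=40), 40, seed=0)

    def test_centroids_frozen_during_sleep(self):
        _, truth = simulate_behavior_trace(0.87, 300, 60, 60, seed=2)
        render_larva_video(truth, MotionParams(), 80, seed=3)
        for s, e in truth.true_bouts:
            seg = truth.true_centroids[s:e]
            assert np.allclose(seg, seg[0])

    def test_wake_displacement_matches_programmed_speed(self):
        """Mean per-wake-frame centroid displacement recorded in the truth
        path must match crawl_speed_mean / fps within 10%."""
        m = MotionParams()
        steps = []
        for seed in range(5):
            _, truth = simulate_behavior_trace(0.87, 2000, 120, 40, seed=seed)
            render_larva_video(truth, m, 96, seed=seed + 50)
            d = np.linalg.norm(np.diff(truth.true_centroids, axis=0), axis=1)
            steps.extend(d[truth.state_sequence[1:]])
        assert np.mean(steps) == pytest.approx(m.crawl_speed_mean / m.fps, rel=0.10)

    def test_noise_monotonicity_on_inactive_frames(self):
        """Raising noise_sd never decreases the variance of pixel-change
        scores on quiescent frames."""
        from larvasleep.activity import pixel_change_scores
        variances = []
        for sd in (0.0, 2.0, 6.0):
            _, truth = simulate_behavior_trace(0.87, 300, 0, 60, seed=0)
            stack = render_larva_video(truth, MotionParams(noise_sd=sd), 80, seed=4)
            scores = pixel_change_scores(stack, noise_floor=3)
            variances.append(scores.scores[1:].var())
        assert variances == sorted(variances)


class TestDAMSeries:
    def test_empty_schedule_has_no_zero_bins(self):
        s = simulate_dam_series([], mean_counts_awake=5, n_minutes=500, seed=0)
        assert (s.channel(1) >= 1).all()

    def test_full_schedule_all_zero(self):
        s = simulate_dam_series([(0, 100)], 5, 100, seed=0)
        assert (s.channel(1) == 0).all()

    def test_zero_bin_count_matches_schedule(self):
        schedule = [(0, 200), (400, 700), (1000, 1100)]  # 600 sleep minutes
        s = simulate_dam_series(schedule, 5, 1440, seed=2)
        assert int((s.channel(1) == 0).sum()) == 600

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_dam_series([(0, 10), (5, 15)], 5, 100, seed=0)

    def test_seed_determinism(self):
        a = simulate_dam_series([(10, 30)], 4, 200, seed=6)
        b = simulate_dam_series([(10, 30)], 4, 200, seed=6)
        assert np.array_equal(a.counts, b.counts)


class TestTranslocationImage:
    def test_half_fraction_equal_means_no_noise(self):
        img, _ = render_translocation_image(0.5, noise_sd=0)
        g = CellGeometry()
        nuc, cyto = g.nuclear_mask(), g.cell_mask() & ~g.nuclear_mask()
        assert img[0][nuc].mean() == pytest.approx(img[0][cyto].mean())

    def test_fraction_one_no_signal_outside_nucleus(self):
        img, _ = render_translocation_image(1.0, noise_sd=0)
        g = CellGeometry()
        assert np.all(img[0][~g.nuclear_mask()] == 0)

    def test_reporter_total_signal_conserved(self):
        g = CellGeometry()
        for f in (0.0, 0.3, 0.8):
            img, _ = render_translocation_image(f, g, noise_sd=0)
            assert float(img[0].sum()) == pytest.approx(g.total_signal, rel=1e-5)

    def test_pixel_sum_oracle_recovers_fraction(self):
        """Direct summation over the known masks recovers f = 0.7 within
        +-0.02 across 20 seeds at default noise."""
        g = CellGeometry()
        nuc, cyto = g.nuclear_mask(), g.cell_mask() & ~g.nuclear_mask()
        recovered = []
        for seed in range(20):
            img, truth = render_translocation_image(0.7, g, noise_sd=2.0, seed=seed)
            f_nuc, f_cyto = img[0][nuc].mean(), img[0][cyto].mean()
            recovered.append(f_nuc / (f_nuc + f_cyto))
            assert truth.true_nuclear_fraction == 0.7
        assert np.median(recovered) == pytest.approx(0.7, abs=0.02)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            render_translocation_image(1.2)


class TestDyedLarva:
    @pytest.mark.parametrize("s,expect", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_fractions(self, s, expect):
        img, truth = render_dyed_larva(s, seed=0)
        assert truth.true_stain_fraction == expect

    def test_mask_count_oracle(self):
        """Counting stain-class vs body pixels over the known geometry
        recovers the programmed fraction within 0.02."""
        g = BodyGeometry(noise_sd=0)
        img, truth = render_dyed_larva(0.3, g, seed=0)
        body = g.body_mask()
        stain = (img[..., 0].astype(int)
                 - np.maximum(img[..., 1], img[..., 2]).astype(int)) > 40
        assert (stain & body).sum() / body.sum() == pytest.approx(0.30, abs=0.02)
        assert truth.true_stain_fraction == pytest.approx(0.30, abs=0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            render_dyed_larva(-0.1)
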