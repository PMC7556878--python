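"""Locomotion binarization, segmentation and triggered averages."""

import numpy as np
import pytest

from vasopipe import synth
from vasopipe.behavior import (
    LocomotionTrace,
    TriggeredAverage,
    basal_value,
    binarize_locomotion,
    evoked_amplitude,
    extract_lta_events,
    find_stationary_periods,
    locomotion_induced_metric,
    locomotion_triggered_average,
    merge_event_gaps,
    onset_time,
    segment_behavior,
)
from vasopipe.errors import (
    InvalidRateError,
    NoStationaryPeriodError,
    VasopipeError,
)

FS = 1000.0


def mask_from_intervals(intervals, duration_s, fs=FS):
    mask = np.zeros(int(duration_s * fs), dtype=bool)
    for a, b in intervals:
        mask[int(a * fs) : int(b * fs)] = True
    return mask


class TestBinarize:
    def test_constant_velocity_is_stationary(self):
        trace = LocomotionTrace(velocity=np.full(20000, 2.0), sample_rate=FS)
        assert not binarize_locomotion(trace).any()

    def test_low_sample_rate_rejected(self):
        trace = LocomotionTrace(velocity=np.zeros(100), sample_rate=15.0)
        with pytest.raises(InvalidRateError):
            binarize_locomotion(trace)

    def test_step_confined_to_transition(self):
        v = np.zeros(20000)
        v[10000:] = 3.0
        moving = binarize_locomotion(LocomotionTrace(velocity=v, sample_rate=FS))
        on = np.where(moving)[0]
        # the 10 Hz zero-phase filter settles within ~1 s on each side
        assert 10000 - FS < on[0] and on[-1] < 10000 + FS

    def test_bout_samples_covered(self, bout_trace, bout_segmentation):
        true_mask = mask_from_intervals(
            bout_trace.ground_truth["bout_times"], bout_trace.duration
        )
        covered = bout_segmentation.moving[true_mask].mean()
        assert covered >= 0.95


class TestStationaryPeriods:
    def test_all_still_single_full_period(self):
        moving = np.zeros(int(30 * FS), dtype=bool)
        periods = find_stationary_periods(moving, FS)
        assert periods == [(0.0, 30.0)]

    def test_ten_second_gap_gives_seven(self):
        moving = mask_from_intervals([(0, 5), (15, 20)], 20)
        periods = find_stationary_periods(moving, FS)
        assert len(periods) == 1
        t0, t1 = periods[0]
        assert t0 == pytest.approx(7.0, abs=0.01)
        assert t1 == pytest.approx(14.0, abs=0.01)

    def test_short_gap_dropped(self):
        moving = mask_from_intervals([(0, 5), (7.5, 12)], 12)
        assert find_stationary_periods(moving, FS) == []


class TestEventExtraction:
    def test_qualifying_event(self):
        moving = mask_from_intervals([(5.0, 13.0)], 20)
        events = extract_lta_events(moving, FS)
        assert len(events) == 1
        assert events[0][0] == pytest.approx(5.0, abs=0.01)

    def test_short_bout_excluded(self):
        moving = mask_from_intervals([(5.0, 9.0)], 20)
        assert extract_lta_events(moving, FS) == []

    def test_insufficient_pre_quiet_excluded(self):
        moving = mask_from_intervals([(2.0, 3.0), (4.0, 12.0)], 20)
        # merge gap is 1 s, so the 1 s gap joins the bouts; use larger gap
        moving = mask_from_intervals([(2.0, 3.0), (4.2, 12.2)], 20)
        events = extract_lta_events(moving, FS, merge_gap_s=1.0)
        assert events == []

    def test_small_gap_merges_to_one_event(self):
        moving = mask_from_intervals([(5.0, 9.0), (9.5, 13.0)], 20)
        merged = merge_event_gaps(moving, FS)
        events = extract_lta_events(merged, FS)
        assert len(events) == 1
        assert events[0] == (pytest.approx(5.0, abs=0.01), pytest.approx(13.0, abs=0.01))

    def test_programmed_onsets_recovered(self):
        for seed in range(5):
            trace = synth.make_locomotion_trace(
                [(20.0, 28.0), (60.0, 72.0)], duration=100.0, seed=seed, noise_sd=0.1,
            )
            seg = segment_behavior(trace)
            assert len(seg.events) == 2
            for (onset, _), (true_on, _) in zip(seg.events, [(20.0, 28.0), (60.0, 72.0)]):
                assert abs(onset - true_on) <= 0.2


class TestBasalValue:
    def test_constant_trace(self, bout_segmentation):
        values = np.full(960, 20.0)
        assert basal_value(values, 8.0, bout_segmentation) == pytest.approx(20.0)

    def test_dilation_during_bouts_ignored(self, bout_segmentation):
        fs = 8.0
        n = 960
        moving = bout_segmentation.moving_mask_at(fs, n)
        values = np.where(moving, 24.0, 20.0)
        assert basal_value(values, fs, bout_segmentation) == pytest.approx(20.0, abs=0.05)

    def test_no_stationary_periods_raises(self, bout_segmentation):
        from vasopipe.behavior import BehaviorSegmentation

        seg = BehaviorSegmentation(
            moving=np.ones(100, dtype=bool), sample_rate=FS,
            events=[], stationary_periods=[],
        )
        with pytest.raises(NoStationaryPeriodError):
            basal_value(np.ones(100), FS, seg)


def ramp_lta(fs=8.0, start=1.0, stop=3.0, amp=0.15):
    rel = np.arange(int(-2 * fs), int(10 * fs)) / fs
    mean = np.where(
        rel < start, 1.0,
        np.where(rel < stop, 1.0 + amp * (rel - start) / (stop - start), 1.0 + amp),
    )
    return TriggeredAverage(rel_time=rel, mean=mean, sem=np.zeros_like(rel),
                            n_events=3, normalization_reference=20.0)


class TestTriggeredAverage:
    def test_identical_events_zero_sem(self):
        fs = 8.0
        values = np.tile(np.concatenate([np.full(40, 20.0), np.full(120, 23.0)]), 4)
        events = [(t, t + 15.0) for t in (5.0, 25.0, 45.0)]
        lta = locomotion_triggered_average(values, fs, events, 20.0)
        assert lta.n_events == 3
        np.testing.assert_allclose(lta.sem, 0.0, atol=1e-12)

    def test_flat_trace_is_unity(self, bout_segmentation):
        fs = 8.0
        values = np.full(960, 20.0)
        basal = basal_value(values, fs, bout_segmentation)
        lta = locomotion_triggered_average(values, fs, bout_segmentation.events, basal)
        np.testing.assert_allclose(lta.mean, 1.0)
        assert evoked_amplitude(lta) == pytest.approx(0.0, abs=1e-9)

    def test_step_dilation_plateau(self, bout_segmentation):
        fs = 8.0
        n = 960
        moving = bout_segmentation.moving_mask_at(fs, n)
        values = np.where(moving, 23.0, 20.0)
        lta = locomotion_triggered_average(values, fs, bout_segmentation.events, 20.0)
        plateau = lta.mean[(lta.rel_time >= 3) & (lta.rel_time <= 6)]
        assert np.mean(plateau) == pytest.approx(1.15, rel=0.02)

    def test_no_event_inside_trace_raises(self):
        with pytest.raises(VasopipeError):
            locomotion_triggered_average(np.ones(40), 8.0, [(100.0, 110.0)], 1.0)


class TestEvokedAmplitude:
    def test_twenty_percent_plateau(self):
        fs = 8.0
        rel = np.arange(int(-2 * fs), int(10 * fs)) / fs
        mean = np.where((rel >= 2.5) & (rel <= 4.5), 1.2, 1.0)
        lta = TriggeredAverage(rel, mean, np.zeros_like(rel), 2, 20.0)
        assert evoked_amplitude(lta) == pytest.approx(20.0)


class TestOnsetTime:
    @pytest.mark.parametrize("ramp_frames", [4, 8, 16, 32])
    def test_noiseless_ramp_exact(self, ramp_frames):
        fs = 8.0
        est = onset_time(ramp_lta(fs=fs, start=1.0, stop=1.0 + ramp_frames / fs))
        assert not est.degenerate
        assert est.time == pytest.approx(1.0, abs=1.0 / fs)

    def test_flat_lta_raises(self):
        fs = 8.0
        rel = np.arange(int(-2 * fs), int(10 * fs)) / fs
        lta = TriggeredAverage(rel, np.ones_like(rel), np.zeros_like(rel), 2, 20.0)
        with pytest.raises(VasopipeError):
            onset_time(lta)

    def test_ramp_with_noise(self):
        rng = np.random.default_rng(12)
        times = []
        for _ in range(25):
            lta = ramp_lta()
            noisy = lta.mean + rng.normal(0, 0.004, lta.mean.size)
            times.append(onset_time(TriggeredAverage(
                lta.rel_time, noisy, lta.sem, 3, 20.0)).time)
        assert np.mean(times) == pytest.approx(1.0, abs=0.2)

    def test_step_flagged_degenerate(self):
        fs = 8.0
        rel = np.arange(int(-2 * fs), int(10 * fs)) / fs
        mean = np.where(rel < 2.0, 1.0, 1.15)
        est = onset_time(TriggeredAverage(rel, mean, np.zeros_like(rel), 2, 20.0))
        assert est.degenerate
        assert est.time == pytest.approx(2.0, abs=1.0 / fs)


class TestLocomotionInducedMetric:
    @pytest.mark.parametrize("baseline,evoked,expected", [
        (0.90, 1.05, 15.0),
        (1.10, 1.15, 5.0),
        (1.0, 1.0, 0.0),
    ])
    def test_worked_examples(self, baseline, evoked, expected):
        assert locomotion_induced_metric(baseline, evoked) == pytest.approx(expected)

    def test_identity_links_reporting_conventions(self):
        # metric + baseline shift = evoked change relative to vehicle basal
        rng = np.random.default_rng(5)
        for _ in range(20):
            b = rng.uniform(0.7, 1.3)
            e = rng.uniform(0.7, 1.4)
            lhs = locomotion_induced_metric(b, e) + (b - 1.0) * 100.0
            assert lhs == pytest.approx((e - 1.0) * 100.0)
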