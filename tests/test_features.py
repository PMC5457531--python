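"""Feature extraction: speed integration, segmentation, shaking detection."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cubescreen import (
    InsufficientDataError,
    MovementEpisode,
    SampleStream,
    detect_shakings,
    integrate_speed,
    segment_movements,
    summarize_experiment,
)
from cubescreen.errors import FormatError

from oracles import brute_segment, brute_shakings


def make_stream(accel, rate=50.0, cube_id="c1"):
    accel = np.asarray(accel, dtype=float)
    t = np.arange(len(accel)) * 1000.0 / rate
    return SampleStream(cube_id=cube_id, timestamps=t, accel=accel, sampling_rate=rate)


class TestIntegrateSpeed:
    def test_constant_acceleration_closed_form(self):
        # v = a t: 1 m/s^2 for 0.4 s from rest -> 0.4 m/s
        stream = make_stream(np.ones(21), rate=50.0)
        v = integrate_speed(stream, (0, 20))
        assert v[0] == 0.0
        assert v[-1] == pytest.approx(0.4, abs=1.0 / 50.0)

    def test_zero_acceleration_gives_zero_speed(self):
        stream = make_stream(np.zeros(30))
        assert np.all(integrate_speed(stream, (0, 29)) == 0.0)

    def test_half_sine_pulse_matches_analytic_integral(self):
        # a(t) = A sin(pi t / T): integral over [0, T] is 2 A T / pi
        rate, T, A = 100.0, 0.4, 2.0
        t = np.arange(int(T * rate) + 1) / rate
        stream = make_stream(A * np.sin(np.pi * t / T), rate=rate)
        v = integrate_speed(stream, (0, len(t) - 1))
        assert v[-1] == pytest.approx(2 * A * T / np.pi, rel=0.01)

    def test_empty_bounds_is_error(self):
        stream = make_stream(np.ones(10))
        with pytest.raises(InsufficientDataError):
            integrate_speed(stream, (5, 3))


class TestSegmentMovements:
    def test_all_zero_stream_has_no_episodes(self):
        assert segment_movements(make_stream(np.zeros(200))) == []

    def test_accel_decel_pulse_pair_is_one_episode(self):
        # +1 m/s^2 for 200 ms then -1 m/s^2 for 200 ms at 100 Hz
        rate = 100.0
        accel = np.concatenate([np.ones(20), -np.ones(20), np.zeros(50)])
        eps = segment_movements(make_stream(accel, rate=rate), speed_threshold=0.05)
        assert len(eps) == 1
        assert 300.0 <= eps[0].duration_ms <= 400.0

    def test_two_pulse_pairs_are_two_episodes(self):
        rate = 100.0
        pulse = np.concatenate([np.ones(20), -np.ones(20)])
        accel = np.concatenate([pulse, np.zeros(100), pulse, np.zeros(20)])
        eps = segment_movements(make_stream(accel, rate=rate), speed_threshold=0.05)
        assert len(eps) == 2

    def test_non_uniform_timestamps_rejected(self):
        t = np.array([0.0, 20.0, 50.0, 60.0])
        with pytest.raises(FormatError):
            SampleStream(cube_id="c", timestamps=t, accel=np.ones(4), sampling_rate=50.0)

    def test_matches_brute_force_scan_on_random_streams(self, rng):
        for _ in range(60):
            n = int(rng.integers(30, 200))
            # sparse bursts of positive acceleration over a silent baseline
            accel = np.zeros(n)
            for _ in range(int(rng.integers(1, 4))):
                w = int(rng.integers(3, 15))
                i0 = int(rng.integers(0, max(n - w, 1)))
                accel[i0 : i0 + w] += rng.uniform(0.2, 3.0, w)
            stream = make_stream(accel)
            eps = segment_movements(stream, speed_threshold=0.02)
            expected = brute_segment(stream.timestamps, accel, 0.02)
            got = [
                (int(np.flatnonzero(stream.timestamps == e.start_ms)[0]),
                 int(np.flatnonzero(stream.timestamps == e.end_ms)[0]))
                for e in eps
            ]
            assert got == expected


class TestDetectShakings:
    def test_three_sample_mound_is_level_one(self):
        events = detect_shakings(np.array([0.1, 1.0, 0.1]))
        assert len(events) == 1
        assert events[0].level == 1
        assert events[0].peak_index == 1

    def test_flat_segment_has_no_shakings(self):
        assert detect_shakings(np.full(20, 0.7)) == []

    def test_sawtooth_with_five_wide_peaks_gives_five_level_four_events(self):
        h = 5  # samples per flank, >= 4 on each side of every peak
        tooth_up = np.linspace(0.1, 1.0, h + 1)[1:]
        tooth_down = np.linspace(1.0, 0.1, h + 1)[1:]
        a = np.concatenate([[0.1], *([tooth_up, tooth_down] * 5)])
        events = detect_shakings(a)
        assert len(events) == 5
        assert all(e.level == 4 for e in events)

    def test_monotone_rise_is_not_a_shaking(self):
        assert detect_shakings(np.linspace(0.1, 2.0, 15)) == []

    def test_matches_brute_force_scan_on_random_segments(self, rng):
        for _ in range(100):
            a = rng.uniform(0.0, 2.0, int(rng.integers(3, 60)))
            got = [(e.level, e.start_index, e.peak_index, e.end_index) for e in detect_shakings(a)]
            assert got == brute_shakings(a)


def _episode(start_ms, dur_ms, mean_speed, max_speed, max_accel, levels=()):
    speeds = np.array([0.0, max_speed, mean_speed])  # only summaries matter here
    shakings = []
    for i, lvl in enumerate(levels):
        from cubescreen import ShakingEvent

        shakings.append(ShakingEvent(level=lvl, start_index=3 * i, peak_index=3 * i + 1,
                                     end_index=3 * i + 2, peak_accel=max_accel))
    ep = MovementEpisode(
        start_ms=start_ms,
        end_ms=start_ms + dur_ms,
        speeds=speeds,
        max_speed=max_speed,
        mean_speed=mean_speed,
        time_of_max_speed_ms=start_ms,
        max_accel=max_accel,
        shakings=shakings,
    )
    return ep


class TestSummarizeExperiment:
    def test_single_episode_summary_equals_episode_values(self):
        ep = _episode(0.0, 500.0, 0.2, 0.5, 2.0, levels=(1, 3))
        s = summarize_experiment([ep], np.array([7.0, 8.0]))
        assert s.n_movements == 1
        assert s.performance_score == 7.5
        assert s.mean_time_ms == 500.0
        assert s.mean_max_speed == s.highest_max_speed == s.lowest_max_speed == 0.5
        assert s.mean_max_accel == s.highest_max_accel == s.lowest_max_accel == 2.0
        assert (s.mean_shaking_1, s.mean_shaking_2, s.mean_shaking_3, s.mean_shaking_4) == (1, 0, 1, 0)

    def test_two_episode_speed_summaries(self):
        eps = [_episode(0.0, 400.0, 0.1, 0.2, 1.0), _episode(1000.0, 600.0, 0.3, 0.4, 3.0)]
        s = summarize_experiment(eps, np.array([6.0]))
        assert s.mean_max_speed == pytest.approx(0.3)
        assert s.highest_max_speed == pytest.approx(0.4)
        assert s.lowest_max_speed == pytest.approx(0.2)
        assert s.mean_time_ms == pytest.approx(500.0)

    def test_zero_episodes_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            summarize_experiment([], np.array([5.0]))

    def test_shaking_conservation(self, rng):
        # sum over levels of (mean count * n_movements) == total mound count
        eps = []
        total = 0
        for i in range(7):
            levels = tuple(rng.integers(1, 5, size=int(rng.integers(0, 5))))
            total += len(levels)
            eps.append(_episode(1000.0 * i, 300.0, 0.1, 0.3, 1.5, levels=levels))
        s = summarize_experiment(eps, np.array([5.0]))
        reconstructed = (s.mean_shaking_1 + s.mean_shaking_2 + s.mean_shaking_3 + s.mean_shaking_4) * s.n_movements
        assert reconstructed == pytest.approx(total)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(100.0, 2000.0),  # duration
                st.floats(0.01, 0.5),  # mean speed
                st.floats(0.0, 2.0),  # extra on top of mean -> max speed
                st.floats(0.1, 10.0),  # max accel
            ),
            min_size=1,
            max_size=8,
        ),
        ratings=st.lists(st.floats(1.0, 10.0), min_size=1, max_size=4),
    )
    def test_summary_ordering_invariants(self, data, ratings):
        eps = [
            _episode(2000.0 * i, dur, ms, ms + extra, acc)
            for i, (dur, ms, extra, acc) in enumerate(data)
        ]
        s = summarize_experiment(eps, np.array(ratings))
        assert s.lowest_max_speed <= s.mean_max_speed <= s.highest_max_speed
        assert s.lowest_max_accel <= s.mean_max_accel <= s.highest_max_accel
        assert 1.0 <= s.performance_score <= 10.0
        assert s.n_movements == len(eps)
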