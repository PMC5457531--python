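"""Feature extraction: from raw acceleration streams to per-experiment variables.

The pipeline mirrors how the smart cube itself reduces its accelerometer data:

1. instantaneous speed is obtained by integrating acceleration over time,
   restarting from rest between movements;
2. a *movement* is a maximal period in which the integrated speed is high
   enough to conclude the cube is moving;
3. *shakings* are the "mounds" of the instantaneous-acceleration graph inside
   a movement — data between two minima — classified into four levels by how
   many samples flank the peak;
4. the per-movement records are reduced to the 13 per-experiment summary
   variables, joined with the mean expert performance score.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import FormatError, InsufficientDataError
from .types import ExperimentSummary, MovementEpisode, SampleStream, ShakingEvent

__all__ = [
    "integrate_speed",
    "segment_movements",
    "detect_shakings",
    "summarize_experiment",
    "DEFAULT_SPEED_THRESHOLD",
    "DEFAULT_MIN_DURATION_MS",
    "DEFAULT_REST_ACCEL",
]

#: Speed (m/s) above which the cube is considered to be moving.  The detector
#: only requires "a value high enough"; 0.02 m/s rejects integration noise
#: while catching the weakest deliberate movements.
DEFAULT_SPEED_THRESHOLD = 0.02
#: Episodes shorter than this are discarded as single-sample noise.
DEFAULT_MIN_DURATION_MS = 100.0
#: |acceleration| below this value counts as rest; integration restarts there.
DEFAULT_REST_ACCEL = 0.05


def integrate_speed(stream: SampleStream, episode_bounds: tuple[int, int]) -> np.ndarray:
    """Instantaneous speed series over ``episode_bounds`` (inclusive indices).

    Speed is zero at the episode start and accumulates by trapezoidal
    integration of acceleration over time in seconds.
    """
    lo, hi = episode_bounds
    if lo > hi or lo < 0 or hi >= len(stream):
        raise InsufficientDataError("empty or out-of-range episode bounds")
    a = stream.accel[lo : hi + 1]
    t = stream.timestamps[lo : hi + 1] / 1000.0
    if len(a) == 1:
        return np.zeros(1)
    return cumulative_trapezoid(a, t, initial=0.0)


def detect_shakings(accel: np.ndarray, index_offset: int = 0) -> list[ShakingEvent]:
    """Find tremor mounds in an acceleration segment.

    The segment is partitioned at strict interior local minima; each resulting
    piece is a candidate mound with one peak.  With ``s`` the number of samples
    on the narrower side of the peak within its mound, the mound is a shaking
    of level ``min(s, 4)``; pieces whose peak sits on a mound boundary
    (``s = 0``, e.g. a monotone rise) are not shakings.
    """
    a = np.asarray(accel, dtype=float)
    n = len(a)
    if n < 3:
        return []
    interior = np.flatnonzero((a[1:-1] < a[:-2]) & (a[1:-1] < a[2:])) + 1
    bounds = [0, *interior.tolist(), n - 1]
    events: list[ShakingEvent] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        piece = a[b0 : b1 + 1]
        peak = b0 + int(np.argmax(piece))
        s = min(peak - b0, b1 - peak)
        if s == 0:
            continue
        events.append(
            ShakingEvent(
                level=min(s, 4),
                start_index=b0 + index_offset,
                peak_index=peak + index_offset,
                end_index=b1 + index_offset,
                peak_accel=float(a[peak]),
            )
        )
    return events


def segment_movements(
    stream: SampleStream,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    rest_accel: float = DEFAULT_REST_ACCEL,
) -> list[MovementEpisode]:
    """Segment a stream into movement episodes by integrated-speed thresholding.

    Acceleration is integrated sample by sample (signed, trapezoidal); whenever
    |acceleration| drops below ``rest_accel`` the cube is at rest and the
    running speed resets to zero, which prevents drift from accumulating
    between movements.  A maximal run with speed >= ``speed_threshold`` becomes
    an episode; the episode is extended backwards to the point the cube last
    left rest, so the whole burst is analysed.  Episodes shorter than
    ``min_duration_ms`` are discarded.
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    n = len(stream)
    if n == 0:
        return []
    t = stream.timestamps
    a = stream.accel

    # Running speed with rest resets.
    v = np.zeros(n)
    for i in range(1, n):
        if abs(a[i]) < rest_accel:
            v[i] = 0.0
        else:
            v[i] = v[i - 1] + 0.5 * (a[i] + a[i - 1]) * (t[i] - t[i - 1]) / 1000.0
    if abs(a[0]) < rest_accel:
        v[0] = 0.0

    episodes: list[MovementEpisode] = []
    i = 0
    prev_end = -1
    while i < n:
        if v[i] >= speed_threshold:
            # Backtrack to where motion started (last zero-speed sample).
            zeros_before = np.flatnonzero(v[prev_end + 1 : i + 1] == 0.0)
            start = prev_end + 1 + int(zeros_before[-1]) if len(zeros_before) else prev_end + 1
            end = i
            while end + 1 < n and v[end + 1] >= speed_threshold:
                end += 1
            _append_episode(episodes, stream, start, end, min_duration_ms)
            prev_end = end
            i = end + 1
        else:
            i += 1
    return episodes


def _append_episode(
    episodes: list[MovementEpisode],
    stream: SampleStream,
    start: int,
    end: int,
    min_duration_ms: float,
) -> None:
    t = stream.timestamps
    duration = t[end] - t[start]
    if duration < min_duration_ms or end <= start:
        return
    speeds = integrate_speed(stream, (start, end))
    seg = stream.accel[start : end + 1]
    imax = int(np.argmax(speeds))
    episodes.append(
        MovementEpisode(
            start_ms=float(t[start]),
            end_ms=float(t[end]),
            speeds=speeds,
            max_speed=float(speeds.max()),
            mean_speed=float(speeds.mean()),
            time_of_max_speed_ms=float(t[start + imax]),
            max_accel=float(np.max(np.abs(seg))),
            shakings=detect_shakings(seg, index_offset=start),
            cube_id=stream.cube_id,
        )
    )


def summarize_experiment(
    episodes: list[MovementEpisode], ratings: np.ndarray
) -> ExperimentSummary:
    """Reduce per-movement records and expert ratings to the summary variables.

    ``performance_score`` is the mean of the expert ratings; the remaining 13
    variables are the canonical per-experiment reductions: counts, the mean of
    per-movement durations, the mean of per-movement mean speeds ("mean of
    means"), and mean/highest/lowest of the per-movement speed and acceleration
    maxima, plus per-level mean shaking counts.
    """
    ratings = np.atleast_1d(np.asarray(ratings, dtype=float))
    if len(episodes) == 0:
        raise InsufficientDataError("no movement episodes to summarize")
    if ratings.size == 0:
        raise InsufficientDataError("at least one rating is required")
    durations = np.array([e.duration_ms for e in episodes])
    mean_speeds = np.array([e.mean_speed for e in episodes])
    max_speeds = np.array([e.max_speed for e in episodes])
    max_accels = np.array([e.max_accel for e in episodes])
    shak = {
        lvl: np.array([e.shaking_count(lvl) for e in episodes], dtype=float)
        for lvl in (1, 2, 3, 4)
    }
    return ExperimentSummary(
        performance_score=float(ratings.mean()),
        n_movements=len(episodes),
        mean_time_ms=float(durations.mean()),
        mean_speed=float(mean_speeds.mean()),
        mean_max_speed=float(max_speeds.mean()),
        highest_max_speed=float(max_speeds.max()),
        lowest_max_speed=float(max_speeds.min()),
        mean_max_accel=float(max_accels.mean()),
        highest_max_accel=float(max_accels.max()),
        lowest_max_accel=float(max_accels.min()),
        mean_shaking_1=float(shak[1].mean()),
        mean_shaking_2=float(shak[2].mean()),
        mean_shaking_3=float(shak[3].mean()),
        mean_shaking_4=float(shak[4].mean()),
    )
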