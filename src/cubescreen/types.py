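"""Domain containers for cube-play sessions and their per-experiment summaries.

Units follow the conventions of the screening instrument throughout: time in
milliseconds, speed in m/s, acceleration in m/s^2.  A ``SampleStream`` holds the
gravity-free acceleration trace of one cube; collector hardware reports a
non-negative magnitude, but signed traces (explicit decelerations) are accepted
so that analytically constructed inputs can be processed too.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FormatError

__all__ = [
    "SampleStream",
    "ShakingEvent",
    "MovementEpisode",
    "ExperimentSummary",
    "TABLE_COLUMNS",
    "SENSOR_VARIABLES",
]


@dataclass
class SampleStream:
    """Uniformly sampled acceleration-magnitude trace for a single cube.

    Parameters
    ----------
    cube_id : str
        Identifier of the cube that produced the samples.
    timestamps : array of float
        Sample times in milliseconds, strictly increasing with uniform spacing
        equal to ``1000 / sampling_rate``.
    accel : array of float
        Acceleration per sample in m/s^2 (gravity-free magnitude for collector
        data; signed values are tolerated).
    sampling_rate : float
        Sampling frequency in Hz.
    """

    cube_id: str
    timestamps: np.ndarray
    accel: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.timestamps.shape != self.accel.shape:
            raise FormatError("timestamps and accel must have equal length")
        if self.timestamps.ndim != 1:
            raise FormatError("stream arrays must be one-dimensional")
        if len(self.timestamps) >= 2:
            dt = np.diff(self.timestamps)
            expected = 1000.0 / self.sampling_rate
            if np.any(dt <= 0) or not np.allclose(dt, expected, rtol=1e-6, atol=1e-6):
                raise FormatError(
                    "timestamps must be strictly increasing with uniform spacing "
                    f"{expected:g} ms"
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        if len(self.timestamps) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class ShakingEvent:
    """One tremor "mound" in the instantaneous-acceleration graph.

    A mound is the data between two minima of the acceleration trace; its level
    (1-4) is the number of samples flanking the peak on its narrower side,
    capped at 4.
    """

    level: int
    start_index: int
    peak_index: int
    end_index: int
    peak_accel: float

    def __post_init__(self) -> None:
        if not (self.start_index < self.peak_index < self.end_index):
            raise ValueError("shaking event requires start < peak < end")
        if self.level not in (1, 2, 3, 4):
            raise ValueError("shaking level must be in 1..4")


@dataclass
class MovementEpisode:
    """One segmented movement of a cube with its derived kinematics."""

    start_ms: float
    end_ms: float
    speeds: np.ndarray
    max_speed: float
    mean_speed: float
    time_of_max_speed_ms: float
    max_accel: float
    shakings: list[ShakingEvent] = field(default_factory=list)
    cube_id: str = ""

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if not self.end_ms > self.start_ms:
            raise ValueError("episode must have positive duration")
        if not (self.start_ms <= self.time_of_max_speed_ms <= self.end_ms):
            raise ValueError("time of max speed must lie within the episode")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def shaking_count(self, level: int) -> int:
        return sum(1 for s in self.shakings if s.level == level)


# Canonical column names for the per-experiment summary table, keyed by the
# attribute names of ExperimentSummary.
TABLE_COLUMNS: dict[str, str] = {
    "performance_score": "Performance scores",
    "n_movements": "Number of movements",
    "mean_time_ms": "Mean time of movement",
    "mean_speed": "Mean speed of movement",
    "mean_max_speed": "Mean of maximum speed",
    "highest_max_speed": "Highest maximum speed",
    "lowest_max_speed": "Lowest maximum speed",
    "mean_max_accel": "Maximum acceleration of movement",
    "highest_max_accel": "Highest maximum acceleration",
    "lowest_max_accel": "Lowest maximum acceleration",
    "mean_shaking_1": "Mean of shaking (level 1)",
    "mean_shaking_2": "Mean of shaking (level 2)",
    "mean_shaking_3": "Mean of shaking (level 3)",
    "mean_shaking_4": "Mean of shaking (level 4)",
}

#: The 13 sensor-derived summary variables (everything except the expert score).
SENSOR_VARIABLES: list[str] = [v for k, v in TABLE_COLUMNS.items() if k != "performance_score"]


@dataclass
class ExperimentSummary:
    """The per-experiment analysis variables for one child-session.

    Houses the expert performance score plus the 13 sensor-derived variables:
    counts, mean movement time, speed summaries, acceleration summaries and the
    four per-level mean shaking counts.
    """

    performance_score: float
    n_movements: int
    mean_time_ms: float
    mean_speed: float
    mean_max_speed: float
    highest_max_speed: float
    lowest_max_speed: float
    mean_max_accel: float
    highest_max_accel: float
    lowest_max_accel: float
    mean_shaking_1: float
    mean_shaking_2: float
    mean_shaking_3: float
    mean_shaking_4: float

    def __post_init__(self) -> None:
        if self.n_movements < 1:
            raise ValueError("summary requires at least one movement")
        if not (1.0 <= self.performance_score <= 10.0):
            raise ValueError("performance score must lie in [1, 10]")
        tol = 1e-9
        if not (self.lowest_max_speed <= self.mean_max_speed + tol
                and self.mean_max_speed <= self.highest_max_speed + tol):
            raise ValueError("speed summaries must be ordered lowest <= mean <= highest")
        if not (self.lowest_max_accel <= self.mean_max_accel + tol
                and self.mean_max_accel <= self.highest_max_accel + tol):
            raise ValueError("acceleration summaries must be ordered lowest <= mean <= highest")

    def to_row(self) -> dict[str, float]:
        """Return the summary as a dict keyed by canonical column names."""
        return {col: getattr(self, attr) for attr, col in TABLE_COLUMNS.items()}
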