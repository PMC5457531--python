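"""Experiment-file I/O: a JSON container for cube-play sessions.

An experiment file holds either raw per-cube sample streams ("raw" payload)
or already-reduced per-movement records ("summary" payload) — exactly one of
the two.  Times are milliseconds, accelerations m/s^2, speeds m/s.  Files are
written with deterministic key ordering so identical inputs produce
byte-identical output, and carry a provenance note stating that transport
encryption is not applied by this implementation.
"""
from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import FormatError
from .types import SampleStream

__all__ = [
    "SCHEMA_VERSION",
    "StreamRecord",
    "MovementRecord",
    "ExperimentFile",
    "read_experiment",
    "write_experiment",
]

SCHEMA_VERSION = "1.0"


def _finite(values: list[float], what: str) -> list[float]:
    if any(not math.isfinite(v) for v in values):
        raise ValueError(f"{what} contains non-finite values")
    return values


class StreamRecord(BaseModel):
    """Raw samples for one cube."""

    model_config = ConfigDict(extra="forbid")

    cube_id: str = Field(min_length=1)
    sampling_rate: float = Field(gt=0)
    timestamps_ms: list[float]
    accel_ms2: list[float]

    @field_validator("timestamps_ms", "accel_ms2")
    @classmethod
    def _check_finite(cls, v, info):
        return _finite(v, info.field_name)

    @model_validator(mode="after")
    def _check_lengths(self):
        if len(self.timestamps_ms) != len(self.accel_ms2):
            raise ValueError("timestamps_ms and accel_ms2 must have equal length")
        return self

    def to_stream(self) -> SampleStream:
        return SampleStream(
            cube_id=self.cube_id,
            timestamps=self.timestamps_ms,
            accel=self.accel_ms2,
            sampling_rate=self.sampling_rate,
        )

    @classmethod
    def from_stream(cls, stream: SampleStream) -> "StreamRecord":
        return cls(
            cube_id=stream.cube_id,
            sampling_rate=stream.sampling_rate,
            timestamps_ms=[float(t) for t in stream.timestamps],
            accel_ms2=[float(a) for a in stream.accel],
        )


class MovementRecord(BaseModel):
    """One already-reduced movement (summary payload mode)."""

    model_config = ConfigDict(extra="forbid")

    cube_id: str = Field(min_length=1)
    start_ms: float
    end_ms: float
    max_speed_ms: float
    mean_speed_ms: float
    time_of_max_speed_ms: float
    max_accel_ms2: float
    shaking_levels: list[int] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        if not self.end_ms > self.start_ms:
            raise ValueError("movement must have positive duration")
        if any(lvl not in (1, 2, 3, 4) for lvl in self.shaking_levels):
            raise ValueError("shaking levels must be in 1..4")
        return self


class ExperimentFile(BaseModel):
    """One child-session experiment container (streams XOR movements)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    child_id: str = Field(min_length=1)
    professional_id: str = Field(min_length=1)
    session_id: str = Field(min_length=1)
    activity: str = "cube_tower"
    timestamp: str = "1970-01-01T00:00:00Z"
    provenance: str = "no-crypto: transport encryption not applied by this implementation"
    streams: list[StreamRecord] | None = None
    movements: list[MovementRecord] | None = None

    @model_validator(mode="after")
    def _payload_mode(self):
        if (self.streams is None) == (self.movements is None):
            raise ValueError("exactly one of streams/movements must be present")
        return self

    @property
    def mode(self) -> str:
        return "raw" if self.streams is not None else "summary"

    def sample_streams(self) -> list[SampleStream]:
        if self.streams is None:
            raise FormatError("experiment file holds summary records, not raw streams")
        return [s.to_stream() for s in self.streams]


def read_experiment(path: str | Path) -> ExperimentFile:
    """Load and validate an experiment JSON file."""
    path = Path(path)
    try:
        payload: dict[str, Any] = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not well-formed JSON: {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"unknown schema_version {version!r} (this reader supports {SCHEMA_VERSION!r})"
        )
    try:
        return ExperimentFile.model_validate(payload)
    except ValueError as exc:
        raise FormatError(f"invalid experiment file {path}: {exc}") from exc


def write_experiment(experiment: ExperimentFile, path: str | Path) -> None:
    """Write an experiment file with deterministic key ordering.

    Non-finite sample values are rejected at validation and again at
    serialization (``allow_nan=False``).
    """
    path = Path(path)
    payload = experiment.model_dump(mode="json", exclude_none=True)
    text = json.dumps(payload, sort_keys=True, indent=1, allow_nan=False)
    path.write_text(text + "\n")
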