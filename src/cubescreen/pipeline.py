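"""High-level pipeline steps tying extraction, validation and scoring together."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .factor import PrincipalAxisFactoring
from .features import (
    DEFAULT_MIN_DURATION_MS,
    DEFAULT_REST_ACCEL,
    DEFAULT_SPEED_THRESHOLD,
    segment_movements,
    summarize_experiment,
)
from .regression import ols_regress
from .reliability import InterraterReliability
from .types import SENSOR_VARIABLES, ExperimentSummary, SampleStream

logger = logging.getLogger("cubescreen")

__all__ = ["extract_summary", "validate_cohort"]


def extract_summary(
    streams: list[SampleStream],
    ratings,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    rest_accel: float = DEFAULT_REST_ACCEL,
) -> ExperimentSummary:
    """Segment all cube streams of one session and reduce to summary variables."""
    episodes = []
    for stream in streams:
        episodes.extend(
            segment_movements(
                stream,
                speed_threshold=speed_threshold,
                min_duration_ms=min_duration_ms,
                rest_accel=rest_accel,
            )
        )
    if not episodes:
        raise InsufficientDataError("no movements detected in any stream")
    episodes.sort(key=lambda e: (e.cube_id, e.start_ms))
    return summarize_experiment(episodes, np.asarray(ratings, dtype=float))


def validate_cohort(
    summaries: pd.DataFrame,
    ratings: np.ndarray | None = None,
    n_factors: int = 3,
) -> tuple[dict, pd.DataFrame]:
    """Run the full psychometric validation on a cohort summary table.

    Returns the JSON-ready report (interrater reliability if ratings are
    given; factor analysis; the performance regression and, when an
    "Age (months)" column exists, the age regression) together with the
    per-child factor scores.
    """
    report: dict = {"n_children": int(len(summaries))}
    if ratings is not None:
        icc = InterraterReliability(np.asarray(ratings, dtype=float)).fit()
        report["interrater_reliability"] = icc.to_dict()

    sensor_cols = [c for c in SENSOR_VARIABLES if c in summaries.columns]
    missing = sorted(set(SENSOR_VARIABLES) - set(sensor_cols))
    if missing:
        raise InsufficientDataError(f"summary table lacks columns: {', '.join(missing)}")
    sensors = summaries[sensor_cols].astype(float)
    constant = [c for c in sensor_cols if sensors[c].std(ddof=1) == 0]
    if constant:
        logger.warning("dropping zero-variance column(s): %s", ", ".join(constant))
        sensors = sensors.drop(columns=constant)
    n_factors = min(n_factors, sensors.shape[1] - 1)

    model = PrincipalAxisFactoring(data=sensors, n_factors=n_factors)
    fa = model.fit(rotation="varimax", kaiser_normalize=True).name_factors()
    report["factor_analysis"] = fa.to_dict()
    if constant:
        report["factor_analysis"]["dropped_columns"] = constant

    scores = fa.score(sensors)
    regressions: dict = {}
    perf = summaries["Performance scores"].astype(float).to_numpy()
    regressions["performance"] = ols_regress(perf, scores).to_dict()
    if "Age (months)" in summaries.columns:
        age = summaries["Age (months)"].astype(float).to_numpy()
        regressions["age"] = ols_regress(age, scores).to_dict()
    report["regressions"] = regressions
    return report, scores
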