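"""Fixed-coefficient screening equations and the advisory rule.

The screening instrument scores a child from three standardized factor scores
(trembling, speed, accuracy):

* ``performance = 7.662 + 0.050 T - 0.630 S + 0.665 A`` (SEE 1.556), and
* ``age = 29.015 - 0.152 T + 0.003 S + 1.372 A`` months (SEE 3.637).

Predicted performance is the detection statistic; a low prediction, or an
observed age far ahead of the age the movement profile predicts, triggers the
"monitor" advisory (keep playing, but see a specialist).  The cut-offs are
repository defaults derived from the equations' standard errors of estimate —
the instrument itself publishes no thresholds — and are fully configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ScreeningEquation",
    "ScreeningThresholds",
    "ScreeningResult",
    "PERFORMANCE_EQUATION",
    "AGE_EQUATION",
    "DEFAULT_THRESHOLDS",
    "score_performance",
    "predict_age",
    "advise",
    "screen_child",
]


@dataclass(frozen=True)
class ScreeningEquation:
    """A linear equation in the three standardized factor scores."""

    intercept: float
    coef_trembling: float
    coef_speed: float
    coef_accuracy: float
    see: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.see < 0:
            raise ConfigurationError("standard error of estimate must be >= 0")

    def predict(self, trembling, speed, accuracy):
        """Evaluate the equation; raw model output, never clipped."""
        return (
            self.intercept
            + self.coef_trembling * np.asarray(trembling, dtype=float)
            + self.coef_speed * np.asarray(speed, dtype=float)
            + self.coef_accuracy * np.asarray(accuracy, dtype=float)
        )


#: Performance model: intercept 7.662, SEE 1.556 (score units, 1-10 scale).
PERFORMANCE_EQUATION = ScreeningEquation(
    intercept=7.662,
    coef_trembling=0.050,
    coef_speed=-0.630,
    coef_accuracy=0.665,
    see=1.556,
    label="performance",
)

#: Age model: intercept 29.015 months, SEE 3.637 months.
AGE_EQUATION = ScreeningEquation(
    intercept=29.015,
    coef_trembling=-0.152,
    coef_speed=0.003,
    coef_accuracy=1.372,
    see=3.637,
    label="age_months",
)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Advisory cut-offs (repository defaults, not instrument claims).

    ``performance`` — "monitor" when predicted performance falls below this;
    default is one SEE below the at-mean prediction (7.662 - 1.556 = 6.106).
    ``age_gap_months`` — "monitor" when observed age exceeds predicted age by
    more than this; default one SEE of the age model (3.637 months).
    """

    performance: float = PERFORMANCE_EQUATION.intercept - PERFORMANCE_EQUATION.see
    age_gap_months: float = AGE_EQUATION.see

    def to_dict(self) -> dict[str, float]:
        return {"performance": self.performance, "age_gap_months": self.age_gap_months}


DEFAULT_THRESHOLDS = ScreeningThresholds()

ADVISORY_OK = "ok"
ADVISORY_MONITOR = "monitor"

ADVISORY_MESSAGES = {
    ADVISORY_OK: "the movements and child's interaction are OK",
    ADVISORY_MONITOR: "let the child keep playing but visit the specialist in 3 months",
}


@dataclass
class ScreeningResult:
    """Predicted performance/age and the advisory for one child."""

    predicted_performance: float
    predicted_age: float | None = None
    observed_age: float | None = None
    advisory: str = ADVISORY_OK
    thresholds_used: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "predicted_performance": self.predicted_performance,
            "predicted_age": self.predicted_age,
            "observed_age": self.observed_age,
            "advisory": self.advisory,
            "message": ADVISORY_MESSAGES[self.advisory],
            "thresholds_used": dict(self.thresholds_used),
        }


def score_performance(scores, eq: ScreeningEquation = PERFORMANCE_EQUATION):
    """Predicted performance for factor scores ``(trembling, speed, accuracy)``."""
    t, s, a = scores
    return eq.predict(t, s, a)


def predict_age(scores, eq: ScreeningEquation = AGE_EQUATION):
    """Predicted chronological age (months) for ``(trembling, speed, accuracy)``."""
    t, s, a = scores
    return eq.predict(t, s, a)


def advise(
    predicted_performance: float | None,
    predicted_age: float | None = None,
    observed_age: float | None = None,
    thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS,
) -> ScreeningResult:
    """Apply the advisory rule to predicted values.

    "monitor" when predicted performance is below ``thresholds.performance``,
    or when observed age exceeds predicted age by more than
    ``thresholds.age_gap_months``; otherwise "ok".
    """
    if predicted_performance is None or not np.isfinite(predicted_performance):
        raise ConfigurationError("advise requires a finite predicted_performance")
    flag = predicted_performance < thresholds.performance
    if observed_age is not None and predicted_age is not None:
        flag = flag or (observed_age - predicted_age > thresholds.age_gap_months)
    return ScreeningResult(
        predicted_performance=float(predicted_performance),
        predicted_age=None if predicted_age is None else float(predicted_age),
        observed_age=None if observed_age is None else float(observed_age),
        advisory=ADVISORY_MONITOR if flag else ADVISORY_OK,
        thresholds_used=thresholds.to_dict(),
    )


def screen_child(
    trembling: float,
    speed: float,
    accuracy: float,
    observed_age: float | None = None,
    performance_eq: ScreeningEquation = PERFORMANCE_EQUATION,
    age_eq: ScreeningEquation = AGE_EQUATION,
    thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS,
) -> ScreeningResult:
    """Full screening for one child: both equations plus the advisory."""
    perf = float(score_performance((trembling, speed, accuracy), performance_eq))
    age = float(predict_age((trembling, speed, accuracy), age_eq))
    return advise(perf, age, observed_age, thresholds)
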