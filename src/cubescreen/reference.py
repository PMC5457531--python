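"""Reference three-factor structure of the cube-play summary variables.

The screening instrument's pilot validation identified three latent factors
behind the 13 sensor-derived summary variables:

* **trembling** — mean movement time and the four shaking-level counts;
* **speed** — mean/maximum speed and maximum-acceleration summaries;
* **accuracy** — number of movements (negatively) and the lowest per-movement
  speed/acceleration maxima.

``REFERENCE_LOADINGS`` is the rotated (varimax, Kaiser-normalized) loading
matrix from that validation, used as the default generating structure for
synthetic cohorts and as the template for naming freshly rotated factors.
``REFERENCE_STARS`` marks, per variable, the factor it is assigned to
(its strongest loading).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import SENSOR_VARIABLES

__all__ = ["FACTOR_NAMES", "REFERENCE_LOADINGS", "REFERENCE_STARS", "REFERENCE_VARIANCE_PCT"]

FACTOR_NAMES: list[str] = ["trembling", "speed", "accuracy"]

_LOADINGS = {
    #                                  trembling  speed  accuracy   assigned
    "Number of movements":             (-0.049,   0.294, -0.782),  # accuracy
    "Mean time of movement":           ( 0.983,  -0.048,  0.003),  # trembling
    "Mean speed of movement":          ( 0.015,   0.840,  0.199),  # speed
    "Mean of maximum speed":           (-0.024,   0.943, -0.009),  # speed
    "Highest maximum speed":           (-0.078,   0.723, -0.572),  # speed
    "Lowest maximum speed":            ( 0.035,   0.264,  0.800),  # accuracy
    "Maximum acceleration of movement": (-0.083,  0.809,  0.139),  # speed
    "Highest maximum acceleration":    (-0.090,   0.642, -0.597),  # speed
    "Lowest maximum acceleration":     (-0.044,   0.447,  0.784),  # accuracy
    "Mean of shaking (level 1)":       ( 0.747,  -0.021, -0.229),  # trembling
    "Mean of shaking (level 2)":       ( 0.896,  -0.120, -0.047),  # trembling
    "Mean of shaking (level 3)":       ( 0.892,  -0.024,  0.173),  # trembling
    "Mean of shaking (level 4)":       ( 0.728,   0.022,  0.225),  # trembling
}

_ASSIGNED = {
    "Number of movements": "accuracy",
    "Mean time of movement": "trembling",
    "Mean speed of movement": "speed",
    "Mean of maximum speed": "speed",
    "Highest maximum speed": "speed",
    "Lowest maximum speed": "accuracy",
    "Maximum acceleration of movement": "speed",
    "Highest maximum acceleration": "speed",
    "Lowest maximum acceleration": "accuracy",
    "Mean of shaking (level 1)": "trembling",
    "Mean of shaking (level 2)": "trembling",
    "Mean of shaking (level 3)": "trembling",
    "Mean of shaking (level 4)": "trembling",
}

REFERENCE_LOADINGS = pd.DataFrame(
    [_LOADINGS[v] for v in SENSOR_VARIABLES],
    index=SENSOR_VARIABLES,
    columns=FACTOR_NAMES,
)

REFERENCE_STARS = pd.DataFrame(
    np.array([[_ASSIGNED[v] == f for f in FACTOR_NAMES] for v in SENSOR_VARIABLES]),
    index=SENSOR_VARIABLES,
    columns=FACTOR_NAMES,
)

#: Percent of total variance attributed to each rotated reference factor.
REFERENCE_VARIANCE_PCT = pd.Series([31.386, 24.788, 20.616], index=FACTOR_NAMES)
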