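"""Exception hierarchy for cubescreen."""


class CubeScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CubeScreenError, ValueError):
    """Invalid generator or pipeline configuration (non-positive rates, bad bounds...)."""


class FormatError(CubeScreenError, ValueError):
    """Malformed input data: bad experiment files, non-uniform timestamps, missing fields."""


class InsufficientDataError(CubeScreenError, ValueError):
    """Not enough data to compute a summary or statistic (e.g. zero movements)."""


class DegenerateInputError(CubeScreenError, ValueError):
    """Statistically degenerate input, e.g. constant ratings across all targets."""


class SingularDesignError(CubeScreenError, ValueError):
    """Rank-deficient regression design matrix."""
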