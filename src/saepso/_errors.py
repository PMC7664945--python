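"""Exception types shared across the package."""


class SaepsoError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(SaepsoError, ValueError):
    """Array shapes are inconsistent with the declared model dimensions."""


class NumericError(SaepsoError, FloatingPointError):
    """A computation produced non-finite or out-of-domain values."""


class OptimizerDivergenceError(SaepsoError, RuntimeError):
    """An iterative optimizer increased its cost for too many steps."""


class EvaluationError(SaepsoError, RuntimeError):
    """A user-supplied cost function returned an invalid value."""


class DegenerateInputError(SaepsoError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class StratificationError(SaepsoError, ValueError):
    """A class cannot be represented in both sides of a stratified split."""


class ConfigError(SaepsoError, ValueError):
    """A run configuration is malformed or internally inconsistent."""


class DataError(SaepsoError, ValueError):
    """A data file is unusable (e.g. a feature column is entirely missing)."""
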