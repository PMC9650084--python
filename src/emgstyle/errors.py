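"""Exception types shared across the pipeline."""


class EmgStyleError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmgStyleError, ValueError):
    """A parameter value is outside its valid range or names an unknown option."""


class SignalLengthError(EmgStyleError, ValueError):
    """A signal is too short for the requested operation."""


class DegenerateColumnError(EmgStyleError, ValueError):
    """A feature column is constant and cannot be standardized."""


class DegenerateDesignError(EmgStyleError, ValueError):
    """The class design collapses (e.g. a single class after standardization)."""


class ConditioningError(EmgStyleError, ValueError):
    """A scatter matrix is numerically singular; regularization is required."""


class LabelMismatchError(EmgStyleError, ValueError):
    """The two views do not share the same class set."""


class ClassCoverageError(EmgStyleError, ValueError):
    """A calibration set does not cover every motion class."""
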