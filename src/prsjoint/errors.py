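"""Exception hierarchy shared across the package."""


class PrsJointError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PrsJointError, ValueError):
    """A configuration value is outside its legal range."""


class AlignmentError(PrsJointError, ValueError):
    """Row/variant identifiers of two inputs do not line up."""


class InputError(PrsJointError, ValueError):
    """An input value is malformed (e.g. negative genotype counts)."""


class LDUndefinedError(PrsJointError, ValueError):
    """LD r^2 requested for a constant dosage vector."""


class DegenerateScoreError(PrsJointError, ValueError):
    """PRS standardisation requested for a zero-variance score."""


class SeparationError(PrsJointError, RuntimeError):
    """Perfect separation detected in a logistic fit."""


class NoEventsError(PrsJointError, ValueError):
    """Cox model requested on data without any events."""


class DivergenceError(PrsJointError, RuntimeError):
    """Monotone likelihood / non-convergence in a survival fit."""


class EmptyCellError(PrsJointError, ValueError):
    """A joint-risk grid cell is empty."""


class AliasedColumnWarning(UserWarning):
    """A rank-deficient design column was dropped before fitting."""
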