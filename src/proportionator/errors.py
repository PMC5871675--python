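"""Exception hierarchy.

All package errors derive from :class:`ProportionatorError` so callers (and
the CLI) can distinguish configuration mistakes (exit code 1) from runtime
estimation failures (exit code 2).
"""


class ProportionatorError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ProportionatorError, ValueError):
    """A parameter or configuration value violates a precondition."""


class NoSignalError(ProportionatorError):
    """The supersection contains no specific-stain pixels (Z == 0); PPS
    sampling is impossible."""


class UndefinedCEError(ProportionatorError):
    """A coefficient of error is requested where it is undefined (zero count
    or zero mean)."""


class EstimationImpossibleError(ProportionatorError):
    """Estimation cannot proceed (missing counts, or every hit unusable)."""
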