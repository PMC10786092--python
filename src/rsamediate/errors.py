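"""Exception types shared across the package."""


class RsamediateError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RsamediateError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class MissingConditionError(RsamediateError, ValueError):
    """A required experimental condition has no trials."""


class DegenerateDataError(RsamediateError, ValueError):
    """Input is degenerate (zero variance, collinear, singular, or empty)."""


class EmptyResultError(RsamediateError, ValueError):
    """An operation removed every trial or participant."""
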