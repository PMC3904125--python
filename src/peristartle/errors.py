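"""Exception hierarchy shared across the package."""


class PeristartleError(Exception):
    """Base class for all package errors."""


class ConfigError(PeristartleError, ValueError):
    """A configuration field is invalid; the message names the field."""


class InputError(PeristartleError, ValueError):
    """An input value violates an operation's preconditions."""


class DegenerateDataError(PeristartleError, ValueError):
    """Data admit no well-defined statistic (e.g. zero-variance nonzero paired shift)."""


class AnalysisError(PeristartleError, RuntimeError):
    """A pipeline comparison cannot be run; the message names the comparison."""
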