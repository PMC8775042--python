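"""Exception hierarchy shared across the package."""


class CecgError(Exception):
    """Base class for all cecgclean errors."""


class ConfigurationError(CecgError):
    """A required configuration value (e.g. the sampling rate) is missing."""


class ParseError(CecgError):
    """A signal or annotation file could not be parsed."""


class ValidationError(CecgError):
    """Inputs violate a documented precondition."""


class DegenerateSignalError(CecgError):
    """The signal has zero variance; threshold statistics are undefined.

    Callers running a pipeline should catch this and skip reduction rather
    than abort: a flat record carries no artifacts to remove.
    """
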