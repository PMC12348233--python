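"""Exception hierarchy shared across the pipeline."""


class SpecFuseError(Exception):
    """Base class for all package errors."""


class ConfigError(SpecFuseError):
    """A configuration value is invalid or inconsistent."""


class DataError(SpecFuseError):
    """Input data violate a precondition (shape, coverage, sign, format)."""


class ConvergenceError(SpecFuseError):
    """An iterative fit failed in a way that cannot be reported as a flag."""
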