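"""Exception hierarchy used across the pipeline."""


class SmokegamError(Exception):
    """Base class for all package errors."""


class ArgumentError(SmokegamError, ValueError):
    """Invalid argument value (out of range, wrong shape, unknown option)."""


class ConfigurationError(SmokegamError, ValueError):
    """A configuration that makes the requested computation undefined."""


class GenerationError(SmokegamError, RuntimeError):
    """Synthetic data could not be generated from the supplied inputs."""


class ParseError(SmokegamError, ValueError):
    """An input file failed schema or value validation."""


class ValidationError(SmokegamError, ValueError):
    """A constructed table violates a structural invariant."""


class RankDeficiencyError(SmokegamError, RuntimeError):
    """The model design is rank deficient after exclusions."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConvergenceError(SmokegamError, RuntimeError):
    """The fitting algorithm failed to converge; carries last-iterate state."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
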