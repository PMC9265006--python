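"""Exception hierarchy for the dottask engine."""


class DotTaskError(Exception):
    """Base class for all dottask errors."""


class ConfigurationError(DotTaskError):
    """Infeasible or inconsistent configuration (e.g. dot larger than screen)."""


class PlacementError(DotTaskError):
    """Rejection-sampling budget exhausted while placing stimuli."""


class SpecificationError(DotTaskError):
    """A trial specification violates the task's structural invariants."""


class LogFormatError(DotTaskError):
    """A persisted trial or event log is malformed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
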