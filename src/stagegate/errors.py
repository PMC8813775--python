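"""Exception hierarchy shared across the package."""


class StagegateError(Exception):
    """Base class for all package errors."""


class SchemeFormatError(StagegateError):
    """A scheme file could not be parsed in the named dialect."""


class SchemeValidationError(StagegateError):
    """A scheme violates one or more structural invariants.

    Carries the full list of violation records so callers can report
    every breach at once rather than the first one found.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"scheme validation failed: {lines}")


class DegenerateStageError(StagegateError):
    """A stage metric is undefined (e.g. zero entries in a predecessor)."""


class InsufficientVariationError(StagegateError):
    """Fewer segregating sites are available than downstream demand."""


class ConstraintError(StagegateError):
    """A crossing/selection request exceeds a hard combinatorial cap."""


class ConfigurationError(StagegateError):
    """An experiment or genome configuration is internally inconsistent."""


class StateError(StagegateError):
    """A program-state precondition is unmet (e.g. missing phenotypes)."""


class InvalidNoiseError(StagegateError):
    """A stage noise specification is degenerate (e.g. h^2 = 0)."""
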