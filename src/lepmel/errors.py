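"""Exception hierarchy shared across the package.

Everything derives from :class:`LepmelError` so callers (and the CLI) can
distinguish package failures from programming errors; the subclasses map to
the failure modes the pipeline contracts name.
"""


class LepmelError(Exception):
    """Base class for all package errors."""


class DomainError(LepmelError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class CoverageError(LepmelError, ValueError):
    """A query falls outside the age coverage of a growth reference."""


class ParameterError(LepmelError, ValueError):
    """Invalid simulation or reference-curve parameters."""


class SchemaError(LepmelError, ValueError):
    """A table is missing required columns or has the wrong dialect."""


class ParseError(LepmelError, ValueError):
    """A malformed row in an input file.

    ``line`` is the 1-based line number in the source file (header = line 1).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InputError(LepmelError, ValueError):
    """Structurally valid input that violates an operation's preconditions."""


class ReferentialError(LepmelError, ValueError):
    """Cross-table reference to an unknown id (e.g. variant without participant)."""


class ConfigError(LepmelError, ValueError):
    """Invalid run configuration."""
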