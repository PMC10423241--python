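"""Exception hierarchy shared across the pipeline stages."""


class PainstratError(Exception):
    """Base class for all package errors."""


class SchemaError(PainstratError):
    """Input table or metadata violates the expected schema."""


class TableParseError(PainstratError):
    """A cell could not be parsed as a number or the missing token."""


class DegenerateVariableError(PainstratError):
    """A variable has zero range / zero variance where spread is required."""

    def __init__(self, variable: str, message: str | None = None):
        self.variable = variable
        super().__init__(message or f"variable {variable!r} is degenerate (zero range)")


class EmptySelectionError(PainstratError):
    """A column/row selection matched nothing."""


class ContractError(PainstratError):
    """A documented precondition of an operation was violated."""


class DomainError(PainstratError):
    """A numeric argument is outside the mathematical domain of the operation."""


class FitFailureError(PainstratError):
    """A model fit produced a physically inadmissible result."""


class ConfigurationError(PainstratError):
    """A configuration object is internally inconsistent."""
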