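"""Exception types shared across the package."""


class PitmatchError(Exception):
    """Base class for package errors."""


class SchemaError(PitmatchError):
    """A required column is missing from an input table."""


class RowError(PitmatchError):
    """One or more rows of an input table could not be parsed.

    Carries ``lines``: the 1-based file line numbers of the offending rows.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class ReferenceError_(PitmatchError):
    """A germline reference file is internally inconsistent."""


class ContractError(PitmatchError):
    """An operation was called outside its documented preconditions."""


class ConfigError(PitmatchError):
    """A simulation or pipeline configuration is invalid or infeasible."""
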