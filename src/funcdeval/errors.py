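"""Exception hierarchy shared across the package."""


class FuncdevalError(Exception):
    """Base class for all package-specific errors."""


class OboParseError(FuncdevalError):
    """The OBO file could not be parsed."""


class StructuralError(FuncdevalError):
    """The ontology graph violates a structural requirement (cycle, unreachable root)."""


class UnknownTermError(FuncdevalError, KeyError):
    """A term id could not be resolved against the ontology."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown or unresolvable term id: {self.term!r}"


class ConsistencyError(FuncdevalError):
    """Namespace or cross-reference consistency violated."""


class TableParseError(FuncdevalError):
    """A tabular input file (GAF, TSV, domtblout, pfam2go) is malformed."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class ValidationError(FuncdevalError):
    """Input values violate a precondition (empty list, study not in universe, ...)."""


class ConfigurationError(FuncdevalError):
    """A configuration value is missing or unsatisfiable."""
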