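"""Exception hierarchy for the taxonconcept package."""


class TaxonConceptError(Exception):
    """Base class for all package-specific errors."""


class UnknownConceptError(TaxonConceptError, KeyError):
    """A concept identifier is not present in the store."""


class UnknownNodeError(TaxonConceptError, KeyError):
    """A concept identifier is not a node of the tree (variant) in question."""


class StructuralError(TaxonConceptError, ValueError):
    """A tree variant is not a single rooted tree (cycle, multiple roots, ...)."""


class EmptyScopeError(TaxonConceptError, ValueError):
    """A scope restriction removed every leaf of the tree."""


class EditError(TaxonConceptError, ValueError):
    """A tree edit's preconditions are not met."""


class ChecklistError(TaxonConceptError, ValueError):
    """A checklist violates its own structural invariants."""


class ChecklistParseError(ChecklistError):
    """A checklist file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StoreSchemaError(TaxonConceptError, ValueError):
    """A serialized concept store failed schema validation."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid store document:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


class CombinationBudgetError(TaxonConceptError, RuntimeError):
    """The candidate-combination search space exceeds the configured cap."""
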