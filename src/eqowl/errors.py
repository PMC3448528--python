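"""Exception hierarchy for eqowl.

Validation *reports* (role-base checks, schema audits) are data, not
exceptions; exceptions are reserved for inputs the API cannot accept at all.
"""

from __future__ import annotations


class EqowlError(Exception):
    """Base class for all eqowl errors."""


class CategoryError(EqowlError):
    """A term was used in a slot that requires a different category."""


class RoleBaseViolationError(EqowlError):
    """A statement violates the role base of its governing relation."""


class TaxonomyError(EqowlError):
    """Structurally invalid taxonomy (cycle, bad disjointness, duplicate)."""


class UnknownTermError(EqowlError):
    """A CURIE was referenced that is not declared in the taxonomy."""


class UnsupportedArityError(EqowlError):
    """The scheme cannot express a statement of this arity (classic EQ > 2)."""


class UnsupportedShapeError(EqowlError):
    """The scheme cannot express this statement shape (e.g. relational
    statements under the entity-focused scheme)."""


class MissingRelatorError(EqowlError):
    """relator_based_quality requires an explicit relation (relator) term."""


class NameCollisionError(EqowlError):
    """A generated class/property name collides with existing vocabulary."""


class SchemaError(EqowlError):
    """Annotation-database file violates the three-table schema.

    ``violations`` lists human-readable messages, each carrying the
    offending row number(s).
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class OwlParseError(EqowlError):
    """Input text is outside the supported functional-syntax subset."""

    def __init__(self, message: str, line: int, column: int):
        self.line = line
        self.column = column
        super().__init__(f"{message} (line {line}, column {column})")


class UnknownNodeError(EqowlError):
    """A node id was referenced that is not in the instance graph."""


class SizeLimitError(EqowlError):
    """Input exceeds a configured combinatorial size bound."""


class ConfigError(EqowlError):
    """Generator configuration is invalid or infeasible."""
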