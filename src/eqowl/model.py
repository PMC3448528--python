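"""Core domain model for EQ phenotype descriptions.

The Entity–Quality (EQ) formalism describes a phenotype by combining a
quality class (e.g. PATO's *red*) with one or more entity classes (e.g. an
anatomy term such as *eye*).  A *simple* quality inheres in a single bearer;
a *relational* quality (e.g. *concentration of* iron in spleen) involves
several entities, each filling a named role.  This module defines the shared
vocabulary of the package:

* :class:`Term` — a CURIE-identified class stub,
* :class:`Taxonomy` — atomic subclass DAG plus atomic disjointness,
* :class:`EQStatement` / :class:`PhenotypeProfile` — phenotype descriptions,
* :class:`RelationSpec` — the role base governing a relation,
* the class-expression AST (:class:`Atom`, :class:`And`, :class:`Some`)
  that the compiler emits and the reasoner consumes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Iterator, Optional, Sequence, Tuple, Union

import networkx as nx

from .errors import CategoryError, RoleBaseViolationError, TaxonomyError, UnknownTermError

__all__ = [
    "Category", "Term", "Measurement", "RoleAssignment", "RelationSpec",
    "EQStatement", "PhenotypeProfile", "Taxonomy",
    "PropRef", "ClassExpr", "Atom", "And", "Some",
    "BEARER", "FIXED_PROP_NAMES",
    "INHERES_IN", "TOWARDS", "HAS_QUALITY", "HAS_PHENO", "HAS_ROLE", "PLAYED_BY",
    "make_simple_statement", "make_relational_statement",
    "validate_against_rolebase", "Violation", "ValidationReport",
    "iter_atoms", "iter_props",
]

_CURIE_RE = re.compile(r"^[^\s:]+:[^\s:]+$")

#: Reserved role label marking the inherence slot of a simple quality.
BEARER = "bearer"


class Category(str, enum.Enum):
    """What kind of ontology class a term stands for."""

    ENTITY = "entity"
    QUALITY = "quality"
    RELATION = "relation"
    ROLE = "role"
    QUALIFIER = "qualifier"


@dataclass(frozen=True)
class Term:
    """A CURIE-identified ontology class stub (no axioms of its own)."""

    curie: str
    label: Optional[str] = None
    category: Category = Category.ENTITY

    def __post_init__(self) -> None:
        if not _CURIE_RE.match(self.curie):
            raise ValueError(f"not a PREFIX:LOCAL curie: {self.curie!r}")
        object.__setattr__(self, "category", Category(self.category))

    @property
    def prefix(self) -> str:
        return self.curie.split(":", 1)[0]

    @property
    def local(self) -> str:
        return self.curie.split(":", 1)[1]


@dataclass(frozen=True)
class Measurement:
    """A measured value with a unit carried as an opaque string.

    No unit algebra is attempted; units compare as strings.
    """

    value: Decimal
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", Decimal(self.value))
        if not self.unit:
            raise ValueError("measurement unit must be nonempty")


@dataclass(frozen=True)
class RoleAssignment:
    """One named argument slot of a statement, filled by an entity term.

    The same ``role_label`` may occur more than once in a statement: role
    categories are multiply instantiable, which is how symmetric relations
    (e.g. *distance* between two eyes) are expressed.
    """

    role_label: str
    filler: Term

    def __post_init__(self) -> None:
        if not self.role_label:
            raise ValueError("role_label must be nonempty")
        if self.filler.category is not Category.ENTITY:
            raise CategoryError(
                f"role filler must be an entity term, got {self.filler.category.value} "
                f"({self.filler.curie})"
            )


@dataclass(frozen=True)
class RelationSpec:
    """Role base of a relation: which role categories its arguments may fill.

    ``max_arity=None`` means unbounded.  ``allow_repeats`` permits several
    arguments to instantiate the same role category (symmetric relations).
    """

    relation: Term
    role_base: Tuple[str, ...]
    min_arity: int = 2
    max_arity: Optional[int] = None
    allow_repeats: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "role_base", tuple(self.role_base))
        if self.relation.category is not Category.RELATION:
            raise CategoryError(f"relation term required, got {self.relation.category.value}")
        if not self.role_base:
            raise ValueError("role_base must be nonempty")
        if self.min_arity < 1:
            raise ValueError("min_arity must be >= 1")
        if self.max_arity is not None and self.max_arity < self.min_arity:
            raise ValueError("max_arity must be >= min_arity")


@dataclass(frozen=True)
class EQStatement:
    """One phenotype description.

    A simple statement has exactly one role labeled :data:`BEARER`; a
    relational statement carries an ordered list of named role assignments
    and, optionally, an explicit relation (relator) term — required only by
    the relator-based-quality compilation scheme.
    """

    quality: Term
    roles: Tuple[RoleAssignment, ...]
    relation: Optional[Term] = None
    qualifier: Optional[Term] = None
    measurement: Optional[Measurement] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "roles", tuple(self.roles))
        if self.quality.category is not Category.QUALITY:
            raise CategoryError(
                f"quality term required, got {self.quality.category.value} ({self.quality.curie})"
            )
        if not self.roles:
            raise ValueError("a statement needs at least one role assignment")
        if self.relation is not None and self.relation.category is not Category.RELATION:
            raise CategoryError(f"relation term required, got {self.relation.category.value}")
        if self.qualifier is not None and self.qualifier.category not in (
            Category.QUALIFIER,
            Category.QUALITY,
        ):
            raise CategoryError(
                f"qualifier must be a qualifier/quality term, got {self.qualifier.category.value}"
            )
        labels = [r.role_label for r in self.roles]
        if BEARER in labels and len(labels) > 1:
            raise ValueError(f"reserved role label {BEARER!r} only valid in a simple statement")

    @property
    def arity(self) -> int:
        return len(self.roles)

    @property
    def is_simple(self) -> bool:
        return len(self.roles) == 1 and self.roles[0].role_label == BEARER


@dataclass(frozen=True)
class PhenotypeProfile:
    """An ordered combination of EQ statements under one identifier."""

    profile_id: str
    statements: Tuple[EQStatement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "statements", tuple(self.statements))
        if not self.statements:
            raise ValueError("profile must contain at least one statement")
        if not self.profile_id:
            raise ValueError("profile_id must be nonempty")


# ---------------------------------------------------------------------------
# Taxonomy


class Taxonomy:
    """Atomic subclass DAG plus atomic disjointness pairs.

    This is the background TBox for satisfiability and subsumption: the only
    axioms are told subsumptions between atomic classes and disjointness
    between atomic classes (inherited downward to all descendants).
    """

    def __init__(
        self,
        terms: Iterable[Term] = (),
        subclass_edges: Iterable[Tuple[str, str]] = (),
        disjoint_pairs: Iterable[Tuple[str, str]] = (),
    ) -> None:
        self._terms: dict[str, Term] = {}
        for t in terms:
            old = self._terms.get(t.curie)
            if old is not None and old != t:
                raise TaxonomyError(f"conflicting declarations for {t.curie}")
            self._terms[t.curie] = t
        self._edges = frozenset((c, p) for c, p in subclass_edges)
        self._dag = nx.DiGraph()
        self._dag.add_nodes_from(self._terms)
        for child, parent in self._edges:
            self._require(child)
            self._require(parent)
            self._dag.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise TaxonomyError(f"subclass edges contain a cycle: {cycle}")
        pairs = set()
        for a, b in disjoint_pairs:
            self._require(a)
            self._require(b)
            if a == b:
                raise TaxonomyError(f"{a} declared disjoint with itself")
            pairs.add(frozenset((a, b)))
        self._disjoint = frozenset(pairs)
        self._anc_cache: dict[str, frozenset] = {}
        for pair in self._disjoint:
            a, b = sorted(pair)
            if b in self.ancestors(a) or a in self.ancestors(b):
                raise TaxonomyError(f"{a} and {b} are disjoint but hierarchically related")

    def _require(self, curie: str) -> None:
        if curie not in self._terms:
            raise UnknownTermError(f"undeclared term: {curie}")

    # -- accessors ---------------------------------------------------------

    @property
    def terms(self) -> dict[str, Term]:
        return dict(self._terms)

    @property
    def subclass_edges(self) -> frozenset:
        return self._edges

    @property
    def disjoint_pairs(self) -> frozenset:
        return self._disjoint

    def __contains__(self, curie: str) -> bool:
        return curie in self._terms

    def term(self, curie: str) -> Term:
        self._require(curie)
        return self._terms[curie]

    def ancestors(self, curie: str, include_self: bool = False) -> frozenset:
        """Transitive reachability over subclass edges (strict by default)."""
        self._require(curie)
        if curie not in self._anc_cache:
            self._anc_cache[curie] = frozenset(nx.descendants(self._dag, curie))
        anc = self._anc_cache[curie]
        return anc | {curie} if include_self else anc

    def is_subclass_of(self, sub: str, sup: str) -> bool:
        """Reflexive told subsumption between atomic classes."""
        return sup == sub or sup in self.ancestors(sub)

    def effectively_disjoint(self, a: str, b: str) -> bool:
        """True iff some ancestor-or-self pair of (a, b) is declared disjoint.

        Symmetric in its arguments.
        """
        if not self._disjoint:
            self._require(a)
            self._require(b)
            return False
        anc_a = self.ancestors(a, include_self=True)
        anc_b = self.ancestors(b, include_self=True)
        return any(
            frozenset((x, y)) in self._disjoint for x in anc_a for y in anc_b
        )

    def with_terms(self, extra: Iterable[Term]) -> "Taxonomy":
        """A copy of this taxonomy with additional (unrelated) term stubs."""
        return Taxonomy(
            list(self._terms.values()) + list(extra),
            self._edges,
            [tuple(sorted(p)) for p in self._disjoint],
        )


# ---------------------------------------------------------------------------
# Class-expression AST

#: Auxiliary object properties with a fixed meaning across schemes.
FIXED_PROP_NAMES = frozenset(
    {"inheresIn", "towards", "hasQuality", "hasPheno", "hasRole", "playedBy"}
)

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


@dataclass(frozen=True)
class PropRef:
    """Reference to an OWL object property.

    ``fixed`` names are the scheme-independent auxiliaries (inheresIn,
    towards, hasQuality, hasPheno, hasRole, playedBy); ``generated`` names
    are derived deterministically from role labels by the compiler.
    """

    name: str
    kind: str = "fixed"

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "generated"):
            raise ValueError(f"bad PropRef kind: {self.kind!r}")
        if self.kind == "fixed" and self.name not in FIXED_PROP_NAMES:
            raise ValueError(f"not a fixed property name: {self.name!r}")
        if not _NAME_RE.match(self.name):
            raise ValueError(f"bad property name: {self.name!r}")


INHERES_IN = PropRef("inheresIn")
TOWARDS = PropRef("towards")
HAS_QUALITY = PropRef("hasQuality")
HAS_PHENO = PropRef("hasPheno")
HAS_ROLE = PropRef("hasRole")
PLAYED_BY = PropRef("playedBy")


class ClassExpr:
    """Base class of the expression AST (Atom | And | Some)."""

    def key(self) -> str:
        """Deterministic structural serialization (order-preserving)."""
        raise NotImplementedError


@dataclass(frozen=True)
class Atom(ClassExpr):
    """An atomic class, referencing a term."""

    term: Term

    def key(self) -> str:
        return self.term.curie


@dataclass(frozen=True)
class And(ClassExpr):
    """Intersection of two or more class expressions."""

    conjuncts: Tuple[ClassExpr, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conjuncts", tuple(self.conjuncts))
        if len(self.conjuncts) < 2:
            raise ValueError("And requires at least two conjuncts")

    def key(self) -> str:
        return "and(" + ",".join(c.key() for c in self.conjuncts) + ")"


@dataclass(frozen=True)
class Some(ClassExpr):
    """Existential restriction ∃prop.filler."""

    prop: PropRef
    filler: ClassExpr

    def key(self) -> str:
        return f"some({self.prop.kind}:{self.prop.name},{self.filler.key()})"


def iter_atoms(expr: ClassExpr) -> Iterator[Atom]:
    """Depth-first iteration over all Atom nodes of an expression."""
    if isinstance(expr, Atom):
        yield expr
    elif isinstance(expr, And):
        for c in expr.conjuncts:
            yield from iter_atoms(c)
    elif isinstance(expr, Some):
        yield from iter_atoms(expr.filler)
    else:  # pragma: no cover - guarded by construction
        raise TypeError(f"not a ClassExpr: {expr!r}")


def iter_props(expr: ClassExpr) -> Iterator[PropRef]:
    """Depth-first iteration over all property references of an expression."""
    if isinstance(expr, And):
        for c in expr.conjuncts:
            yield from iter_props(c)
    elif isinstance(expr, Some):
        yield expr.prop
        yield from iter_props(expr.filler)


# ---------------------------------------------------------------------------
# Statement constructors and role-base validation


def make_simple_statement(
    quality: Term,
    bearer: Term,
    qualifier: Optional[Term] = None,
    measurement: Optional[Measurement] = None,
) -> EQStatement:
    """Build a simple statement: ``quality`` inheres in ``bearer``.

    Raises :class:`CategoryError` if the terms have the wrong categories
    (e.g. quality and entity swapped).
    """
    if quality.category is not Category.QUALITY:
        raise CategoryError(f"first argument must be a quality term, got {quality.category.value}")
    if bearer.category is not Category.ENTITY:
        raise CategoryError(f"bearer must be an entity term, got {bearer.category.value}")
    return EQStatement(
        quality=quality,
        roles=(RoleAssignment(BEARER, bearer),),
        qualifier=qualifier,
        measurement=measurement,
    )


def make_relational_statement(
    quality: Term,
    assignments: Sequence[RoleAssignment],
    relation: Optional[Term] = None,
    qualifier: Optional[Term] = None,
    spec: Optional[RelationSpec] = None,
    measurement: Optional[Measurement] = None,
) -> EQStatement:
    """Build a relational statement with named, ordered role assignments.

    Role order is preserved exactly as given (it matters only to the
    classic-EQ slot mapping and to serialization).  Without a governing
    :class:`RelationSpec`, at least two assignments are required; with one,
    the spec's arity bounds apply and violations raise
    :class:`RoleBaseViolationError`.
    """
    assignments = tuple(assignments)
    if spec is None:
        if len(assignments) < 2:
            raise ValueError(
                "relational statement needs >= 2 role assignments "
                "(or a RelationSpec permitting fewer)"
            )
    stmt = EQStatement(
        quality=quality,
        roles=assignments,
        relation=relation,
        qualifier=qualifier,
        measurement=measurement,
    )
    if spec is not None:
        report = validate_against_rolebase(stmt, spec)
        if not report.valid:
            raise RoleBaseViolationError("; ".join(v.message for v in report.violations))
    return stmt


@dataclass(frozen=True)
class Violation:
    """One role-base violation; ``kind`` is a machine-checkable tag."""

    kind: str  # unknown_role | arity | repeated_role | relation_mismatch
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: Tuple[Violation, ...]

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_against_rolebase(stmt: EQStatement, spec: RelationSpec) -> ValidationReport:
    """Check a statement against a relation's role base.

    Violations are returned as data, never raised: unknown role labels,
    arity outside ``[min_arity, max_arity]``, and forbidden repetition of a
    role category.  An empty report means the statement conforms.
    """
    violations: list[Violation] = []
    if stmt.relation is not None and stmt.relation.curie != spec.relation.curie:
        violations.append(
            Violation(
                "relation_mismatch",
                f"statement relation {stmt.relation.curie} does not match "
                f"spec relation {spec.relation.curie}",
            )
        )
    labels = [r.role_label for r in stmt.roles]
    for lbl in labels:
        if lbl not in spec.role_base:
            violations.append(
                Violation("unknown_role", f"role label {lbl!r} not in role base {spec.role_base}")
            )
    n = len(labels)
    if n < spec.min_arity or (spec.max_arity is not None and n > spec.max_arity):
        hi = "unbounded" if spec.max_arity is None else spec.max_arity
        violations.append(
            Violation("arity", f"arity {n} outside [{spec.min_arity}, {hi}]")
        )
    if not spec.allow_repeats:
        seen = set()
        for lbl in labels:
            if lbl in seen and lbl in spec.role_base:
                violations.append(
                    Violation("repeated_role", f"role label {lbl!r} repeated but not repeatable")
                )
            seen.add(lbl)
    return ValidationReport(tuple(violations))
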