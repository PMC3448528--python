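"""Compilation of EQ statements and profiles into OWL class expressions.

Five encoding schemes are supported:

``classic_eq``
    ``Q ⊓ ∃inheresIn.E`` for simple qualities; for binary relational
    qualities the second entity hangs off ``towards``.  Which role filler
    lands in which slot is governed by a configurable *slot map* — the very
    assignment on which modelers disagree, so every relational compilation
    under this scheme logs a warning.
``entity_focused``
    ``E ⊓ ∃hasQuality.Q`` — the entity-centered reading of a simple quality.
``roles_as_properties``
    ``R ⊓ ∃o_role1.E1 ⊓ … ⊓ ∃o_rolen.En`` with one generated object property
    per role category; supports any arity.
``roles_as_classes``
    ``R ⊓ ∃hasRole.(Role_i ⊓ ∃playedBy.E_i) ⊓ …`` with one generated role
    class per role category.
``relator_based_quality``
    ``Q ⊓ ∃inheresIn.(relator-expression)`` where the relator expression is
    the relation compiled under one of the two role-based sub-schemes.  The
    quality then inheres in a single entity (the relator), so measurement
    machinery for unary qualities applies unchanged.

Profiles compose either *naively* (plain intersection of the statement
expressions — known to produce unsatisfiable and permutation-ambiguous
classes) or via the encapsulating ``hasPheno`` property, one
``∃hasPheno.(…)`` conjunct per statement.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

from .errors import (
    MissingRelatorError,
    NameCollisionError,
    UnknownTermError,
    UnsupportedArityError,
    UnsupportedShapeError,
)
from .model import (
    And,
    Atom,
    Category,
    ClassExpr,
    EQStatement,
    FIXED_PROP_NAMES,
    HAS_PHENO,
    HAS_QUALITY,
    HAS_ROLE,
    INHERES_IN,
    PLAYED_BY,
    PhenotypeProfile,
    PropRef,
    Some,
    Taxonomy,
    Term,
    TOWARDS,
    iter_atoms,
    iter_props,
)

__all__ = [
    "SchemeKind", "Scheme", "CLASSIC_EQ", "ENTITY_FOCUSED", "ROLES_AS_PROPERTIES",
    "ROLES_AS_CLASSES", "RELATOR_RP", "RELATOR_RC", "ALL_SCHEMES",
    "DEFAULT_GEN_PREFIX", "role_property", "role_class_term",
    "compile_statement", "compose_profile", "emit_ontology",
    "EmittedOntology", "VocabInventory", "vocab_inventory",
    "generated_class_terms", "taxonomy_from_ontology",
]

logger = logging.getLogger(__name__)

#: Namespace prefix under which generated role classes/properties live.
DEFAULT_GEN_PREFIX = "GEN"

#: Default IRI bound to the empty ("default") prefix in emitted ontologies.
DEFAULT_BASE_IRI = "http://example.org/pheno#"


class SchemeKind(str, enum.Enum):
    CLASSIC_EQ = "classic_eq"
    ENTITY_FOCUSED = "entity_focused"
    ROLES_AS_PROPERTIES = "roles_as_properties"
    ROLES_AS_CLASSES = "roles_as_classes"
    RELATOR_BASED_QUALITY = "relator_based_quality"


_SUB_SCHEMES = (SchemeKind.ROLES_AS_PROPERTIES, SchemeKind.ROLES_AS_CLASSES)


@dataclass(frozen=True)
class Scheme:
    """A compilation scheme; ``sub_scheme`` is meaningful only for
    relator_based_quality (how the relator itself is encoded)."""

    kind: SchemeKind
    sub_scheme: Optional[SchemeKind] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", SchemeKind(self.kind))
        if self.kind is SchemeKind.RELATOR_BASED_QUALITY:
            sub = self.sub_scheme or SchemeKind.ROLES_AS_PROPERTIES
            if SchemeKind(sub) not in _SUB_SCHEMES:
                raise ValueError(f"invalid sub_scheme: {sub}")
            object.__setattr__(self, "sub_scheme", SchemeKind(sub))
        elif self.sub_scheme is not None:
            raise ValueError("sub_scheme only meaningful for relator_based_quality")

    def __str__(self) -> str:
        if self.kind is SchemeKind.RELATOR_BASED_QUALITY:
            return f"{self.kind.value}:{self.sub_scheme.value}"
        return self.kind.value


CLASSIC_EQ = Scheme(SchemeKind.CLASSIC_EQ)
ENTITY_FOCUSED = Scheme(SchemeKind.ENTITY_FOCUSED)
ROLES_AS_PROPERTIES = Scheme(SchemeKind.ROLES_AS_PROPERTIES)
ROLES_AS_CLASSES = Scheme(SchemeKind.ROLES_AS_CLASSES)
RELATOR_RP = Scheme(SchemeKind.RELATOR_BASED_QUALITY, SchemeKind.ROLES_AS_PROPERTIES)
RELATOR_RC = Scheme(SchemeKind.RELATOR_BASED_QUALITY, SchemeKind.ROLES_AS_CLASSES)

#: Every scheme variant, in a stable order.
ALL_SCHEMES: Tuple[Scheme, ...] = (
    CLASSIC_EQ, ENTITY_FOCUSED, ROLES_AS_PROPERTIES, ROLES_AS_CLASSES, RELATOR_RP, RELATOR_RC,
)

#: Slot maps for classic-EQ relational statements: role index -> property.
SLOT_MAPS: Dict[str, Tuple[PropRef, PropRef]] = {
    "standard": (INHERES_IN, TOWARDS),
    "reversed": (TOWARDS, INHERES_IN),
}


# ---------------------------------------------------------------------------
# Generated vocabulary naming


def _tokens(label: str) -> list:
    toks = [t for t in re.split(r"[^0-9A-Za-z]+", label) if t]
    if not toks:
        raise ValueError(f"role label {label!r} yields no name tokens")
    return toks


def role_property(label: str) -> PropRef:
    """Generated object property for a role category (camel-cased label)."""
    toks = _tokens(label)
    name = toks[0][0].lower() + toks[0][1:] + "".join(t[0].upper() + t[1:] for t in toks[1:])
    if name in FIXED_PROP_NAMES:
        raise NameCollisionError(f"generated property {name!r} collides with a fixed property")
    return PropRef(name, "generated")


def role_class_term(label: str, gen_prefix: str = DEFAULT_GEN_PREFIX) -> Term:
    """Generated role class for a role category (capitalized label)."""
    toks = _tokens(label)
    name = "".join(t[0].upper() + t[1:] for t in toks)
    return Term(f"{gen_prefix}:{name}", label=label, category=Category.ROLE)


# ---------------------------------------------------------------------------
# Statement compilation


def _intersect(parts: Sequence[ClassExpr]) -> ClassExpr:
    flat: list = []
    for p in parts:
        if isinstance(p, And):
            flat.extend(p.conjuncts)
        else:
            flat.append(p)
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


def _head_conjuncts(head: Term, qualifier: Optional[Term]) -> list:
    parts: list = [Atom(head)]
    if qualifier is not None:
        parts.append(Atom(qualifier))
    return parts


def _role_restrictions(stmt: EQStatement, sub: SchemeKind, gen_prefix: str) -> list:
    out = []
    for ra in stmt.roles:
        if sub is SchemeKind.ROLES_AS_PROPERTIES:
            out.append(Some(role_property(ra.role_label), Atom(ra.filler)))
        else:
            out.append(
                Some(
                    HAS_ROLE,
                    And(
                        (
                            Atom(role_class_term(ra.role_label, gen_prefix)),
                            Some(PLAYED_BY, Atom(ra.filler)),
                        )
                    ),
                )
            )
    return out


def compile_statement(
    stmt: EQStatement,
    scheme: Scheme,
    *,
    slot_map: str = "standard",
    gen_prefix: str = DEFAULT_GEN_PREFIX,
) -> ClassExpr:
    """Compile one statement into a class expression under ``scheme``.

    Raises :class:`UnsupportedArityError` for classic EQ at arity > 2 (the
    expressiveness limit of the fixed inheresIn/towards pattern),
    :class:`UnsupportedShapeError` for relational statements under the
    entity-focused scheme, and :class:`MissingRelatorError` when the
    relator-based-quality scheme is applied to a statement without an
    explicit relation term.
    """
    kind = scheme.kind
    if stmt.is_simple and kind is not SchemeKind.ENTITY_FOCUSED:
        # Simple (unary) qualities are not relational: under every
        # quality-headed scheme they keep the plain inherence pattern.
        parts = _head_conjuncts(stmt.quality, stmt.qualifier)
        parts.append(Some(INHERES_IN, Atom(stmt.roles[0].filler)))
        return _intersect(parts)
    if kind is SchemeKind.CLASSIC_EQ:
        if stmt.arity > 2:
            raise UnsupportedArityError(
                f"classic EQ supports relational qualities of arity <= 2, got {stmt.arity}"
            )
        parts = _head_conjuncts(stmt.quality, stmt.qualifier)
        if stmt.is_simple:
            parts.append(Some(INHERES_IN, Atom(stmt.roles[0].filler)))
        else:
            props = SLOT_MAPS[slot_map]
            logger.warning(
                "classic_eq slot mapping is inter-modeler ambiguous: "
                "assigning role %r -> %s%s",
                stmt.roles[0].role_label,
                props[0].name,
                f", role {stmt.roles[1].role_label!r} -> {props[1].name}"
                if stmt.arity == 2
                else "",
            )
            for ra, prop in zip(stmt.roles, props):
                parts.append(Some(prop, Atom(ra.filler)))
        return _intersect(parts)

    if kind is SchemeKind.ENTITY_FOCUSED:
        if not stmt.is_simple:
            raise UnsupportedShapeError(
                "entity_focused compiles only simple (single-bearer) statements"
            )
        qpart: ClassExpr = Atom(stmt.quality)
        if stmt.qualifier is not None:
            qpart = And((Atom(stmt.quality), Atom(stmt.qualifier)))
        return And((Atom(stmt.roles[0].filler), Some(HAS_QUALITY, qpart)))

    if kind in (SchemeKind.ROLES_AS_PROPERTIES, SchemeKind.ROLES_AS_CLASSES):
        head = stmt.relation if stmt.relation is not None else stmt.quality
        parts = _head_conjuncts(head, stmt.qualifier)
        parts.extend(_role_restrictions(stmt, kind, gen_prefix))
        return _intersect(parts)

    if kind is SchemeKind.RELATOR_BASED_QUALITY:
        if stmt.relation is None:
            raise MissingRelatorError(
                f"relator_based_quality requires an explicit relation term "
                f"(statement quality {stmt.quality.curie})"
            )
        inner = _intersect(
            [Atom(stmt.relation)] + _role_restrictions(stmt, scheme.sub_scheme, gen_prefix)
        )
        parts = _head_conjuncts(stmt.quality, stmt.qualifier)
        parts.append(Some(INHERES_IN, inner))
        return _intersect(parts)

    raise ValueError(f"unknown scheme: {scheme}")  # pragma: no cover


def compose_profile(
    profile: PhenotypeProfile,
    scheme: Scheme,
    mode: str,
    *,
    slot_map: str = "standard",
    gen_prefix: str = DEFAULT_GEN_PREFIX,
) -> ClassExpr:
    """Compose a profile's statements into one class expression.

    ``mode="naive"`` intersects the statement expressions directly (the
    composition whose unsatisfiability and permutation collapse this package
    makes checkable); ``mode="haspheno"`` wraps each statement in
    ``∃hasPheno.(…)`` before intersecting.  A single-statement profile
    returns its (possibly wrapped) compilation bare.
    """
    if mode not in ("naive", "haspheno"):
        raise ValueError(f"mode must be 'naive' or 'haspheno', got {mode!r}")
    compiled = [
        compile_statement(s, scheme, slot_map=slot_map, gen_prefix=gen_prefix)
        for s in profile.statements
    ]
    if mode == "haspheno":
        compiled = [Some(HAS_PHENO, c) for c in compiled]
    return _intersect(compiled)


# ---------------------------------------------------------------------------
# Ontology emission


@dataclass
class EmittedOntology:
    """A self-contained ontology image of compiled profiles.

    ``named_class_definitions`` maps a named-class CURIE (the profile id,
    or ``:id`` in the default namespace) to its defining expression.  The
    taxonomy's subclass/disjointness axioms are carried over so the output
    is checkable in isolation.
    """

    prefixes: Dict[str, str]
    declared_classes: frozenset
    declared_object_properties: frozenset
    named_class_definitions: Dict[str, ClassExpr]
    subclass_axioms: Tuple[Tuple[str, str], ...]
    disjoint_axioms: Tuple[Tuple[str, str], ...]

    def validate(self) -> None:
        """Check that everything used in a definition is declared."""
        for name, expr in self.named_class_definitions.items():
            if name not in self.declared_classes:
                raise UnknownTermError(f"named class {name} not declared")
            for atom in iter_atoms(expr):
                if atom.term.curie not in self.declared_classes:
                    raise UnknownTermError(f"atom {atom.term.curie} used but not declared")
            for prop in iter_props(expr):
                if prop not in self.declared_object_properties:
                    raise UnknownTermError(f"property {prop.name} used but not declared")


#: Namespace for named profile classes whose ids are not already CURIEs.
PROFILE_PREFIX = "PHENO"


def _named_class(profile_id: str) -> str:
    return profile_id if ":" in profile_id else f"{PROFILE_PREFIX}:{profile_id}"


def generated_class_terms(expr: ClassExpr, gen_prefix: str = DEFAULT_GEN_PREFIX) -> list:
    """All generated (role-class) terms occurring in an expression."""
    seen: dict[str, Term] = {}
    for atom in iter_atoms(expr):
        if atom.term.prefix == gen_prefix:
            seen.setdefault(atom.term.curie, atom.term)
    return list(seen.values())


def emit_ontology(
    profiles: Sequence[PhenotypeProfile],
    scheme: Scheme,
    mode: str,
    taxonomy: Taxonomy,
    *,
    slot_map: str = "standard",
    gen_prefix: str = DEFAULT_GEN_PREFIX,
) -> EmittedOntology:
    """Compile profiles and assemble a self-contained ontology.

    Every atom referenced by a statement must be declared in ``taxonomy``
    (generated role classes are declared by the emitter itself); a generated
    class CURIE colliding with a declared term raises
    :class:`NameCollisionError`.  Output is deterministic for a fixed input
    ordering.
    """
    definitions: Dict[str, ClassExpr] = {}
    generated: dict[str, Term] = {}
    used_props: set = set()
    for profile in profiles:
        name = _named_class(profile.profile_id)
        if name in definitions:
            raise ValueError(f"duplicate profile id: {profile.profile_id}")
        expr = compose_profile(profile, scheme, mode, slot_map=slot_map, gen_prefix=gen_prefix)
        for atom in iter_atoms(expr):
            curie = atom.term.curie
            if atom.term.prefix == gen_prefix:
                if curie in taxonomy:
                    raise NameCollisionError(
                        f"generated class {curie} collides with a declared term"
                    )
                generated[curie] = atom.term
            elif curie not in taxonomy:
                raise UnknownTermError(f"statement references undeclared term {curie}")
        used_props.update(iter_props(expr))
        definitions[name] = expr

    declared_classes = frozenset(taxonomy.terms) | frozenset(generated) | frozenset(definitions)
    prefixes = {"": DEFAULT_BASE_IRI}
    for curie in declared_classes:
        pfx = curie.split(":", 1)[0]
        prefixes.setdefault(pfx, f"http://example.org/{pfx.lower()}#" if pfx else DEFAULT_BASE_IRI)
    ontology = EmittedOntology(
        prefixes=prefixes,
        declared_classes=declared_classes,
        declared_object_properties=frozenset(used_props),
        named_class_definitions=definitions,
        subclass_axioms=tuple(sorted(taxonomy.subclass_edges)),
        disjoint_axioms=tuple(sorted(tuple(sorted(p)) for p in taxonomy.disjoint_pairs)),
    )
    ontology.validate()
    return ontology


def taxonomy_from_ontology(ontology: EmittedOntology) -> Taxonomy:
    """Rebuild a background taxonomy from an emitted/parsed ontology.

    Declared classes become term stubs (category information is not carried
    by the functional-syntax subset, so entities are assumed); subclass and
    disjointness axioms are taken over verbatim.  Named defined classes are
    included as stubs so their definitions can be checked against it.
    """
    terms = [Term(c) for c in ontology.declared_classes]
    return Taxonomy(terms, ontology.subclass_axioms, ontology.disjoint_axioms)


# ---------------------------------------------------------------------------
# Vocabulary accounting


@dataclass(frozen=True)
class VocabInventory:
    """Generated-vocabulary counts for one statement under one scheme.

    Counts are measured on the compiled expression, never hard-coded:
    ``new_classes`` counts generated role classes (the statement's own
    E/Q/relation terms are excluded); ``new_object_properties`` counts the
    distinct fixed + generated object properties used, excluding hasPheno
    (which belongs to composition, not to the statement encoding).
    """

    scheme: Scheme
    arity: int
    new_classes: int
    new_object_properties: int


def vocab_inventory(
    scheme: Scheme,
    stmt: EQStatement,
    *,
    slot_map: str = "standard",
    gen_prefix: str = DEFAULT_GEN_PREFIX,
) -> VocabInventory:
    """Count the vocabulary a single statement's encoding introduces."""
    expr = compile_statement(stmt, scheme, slot_map=slot_map, gen_prefix=gen_prefix)
    props = {p for p in iter_props(expr) if p != HAS_PHENO}
    classes = {a.term.curie for a in iter_atoms(expr) if a.term.prefix == gen_prefix}
    return VocabInventory(
        scheme=scheme,
        arity=stmt.arity,
        new_classes=len(classes),
        new_object_properties=len(props),
    )
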