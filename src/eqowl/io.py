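"""File formats: the row-wise annotation database, taxonomy and instance
graph TSVs, and the emitted-ontology round trip.

The annotation database is a three-table image in which role-based
information is stored *row-wise*: the phenotype table holds one row per
(p_id, role) with quality/entity/qualifier CURIEs, the entity table carries
annotated entities with opaque attributes, and the annotation table links
entities to phenotype ids, optionally with a measured value and unit.  A
row-wise layout supports relations of any (even variable) arity without
schema changes, at the price of a grouping discipline that the reader
validates.

TSV dialect: UTF-8, tab-separated, one header line, ``#`` comment lines,
no quoting; ids are nonnegative integers; empty cells (and the ``N/A``
rendering) mean "absent".
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import SchemaError, UnknownTermError
from .justify import InstanceGraph
from .model import (
    BEARER,
    Category,
    EQStatement,
    Measurement,
    PhenotypeProfile,
    RoleAssignment,
    Taxonomy,
    Term,
    make_simple_statement,
)
from .owlfs import parse_ontology, write_ontology

__all__ = [
    "PhenotypeRow", "EntityRow", "AnnotationRow", "AnnotationDB",
    "read_annotation_db", "write_annotation_db", "db_equal_up_to_ids",
    "db_to_profiles", "profiles_to_db",
    "read_taxonomy", "write_taxonomy",
    "read_instance_graph", "write_instance_graph",
    "parse_owl_subset", "write_owl_subset",
]

_PHENOTYPE_HEADER = ["r_id", "p_id", "quality", "role", "entity", "qualifier"]
_ANNOTATION_HEADER = ["e_id", "p_id", "measured_value", "measuring_unit"]
_NA_STRINGS = {"", "N/A", "*N/A*"}


@dataclass(frozen=True)
class PhenotypeRow:
    r_id: int
    p_id: int
    quality: str
    role: Optional[str]
    entity: str
    qualifier: Optional[str]


@dataclass(frozen=True)
class EntityRow:
    e_id: int
    attributes: Tuple[Tuple[str, str], ...] = ()  # opaque, never interpreted


@dataclass(frozen=True)
class AnnotationRow:
    e_id: int
    p_id: int
    measured_value: Optional[Decimal]
    measuring_unit: Optional[str]


@dataclass
class AnnotationDB:
    """In-memory image of the three-table annotation schema."""

    phenotype_rows: List[PhenotypeRow] = field(default_factory=list)
    entity_rows: List[EntityRow] = field(default_factory=list)
    annotation_rows: List[AnnotationRow] = field(default_factory=list)

    def validate(self) -> List[str]:
        """Return schema-invariant violations (empty list means valid)."""
        violations: List[str] = []
        seen_r = {}
        qualifiers: Dict[int, set] = {}
        for i, row in enumerate(self.phenotype_rows):
            if row.r_id in seen_r:
                violations.append(
                    f"phenotype rows {seen_r[row.r_id]} and {i}: duplicate r_id {row.r_id}"
                )
            seen_r[row.r_id] = i
            qualifiers.setdefault(row.p_id, set()).add(row.qualifier)
        for p_id, quals in sorted(qualifiers.items()):
            if len(quals) > 1:
                violations.append(
                    f"p_id {p_id}: rows carry different qualifiers {sorted(map(str, quals))}"
                )
        declared_p = {row.p_id for row in self.phenotype_rows}
        seen_ep = {}
        for i, row in enumerate(self.annotation_rows):
            key = (row.e_id, row.p_id)
            if key in seen_ep:
                violations.append(
                    f"annotation rows {seen_ep[key]} and {i}: duplicate (e_id, p_id) {key}"
                )
            seen_ep[key] = i
            if row.p_id not in declared_p:
                violations.append(f"annotation row {i}: p_id {row.p_id} not in phenotype table")
            if (row.measured_value is None) != (row.measuring_unit is None):
                violations.append(
                    f"annotation row {i}: measured_value and measuring_unit "
                    "must be both present or both absent"
                )
        return violations


def _opt(cell: str) -> Optional[str]:
    cell = cell.strip()
    return None if cell in _NA_STRINGS else cell


def _read_rows(path) -> Tuple[List[str], List[Tuple[int, List[str]]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        header: Optional[List[str]] = None
        rows: List[Tuple[int, List[str]]] = []
        for lineno, raw in enumerate(reader, start=1):
            if not raw or (raw[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in raw]
            else:
                rows.append((lineno, raw))
    if header is None:
        raise SchemaError([f"{path}: missing header line"])
    return header, rows


def _int(cell: str, where: str, violations: List[str]) -> Optional[int]:
    try:
        value = int(cell)
    except ValueError:
        violations.append(f"{where}: not an integer: {cell!r}")
        return None
    if value < 0:
        violations.append(f"{where}: ids must be nonnegative, got {value}")
        return None
    return value


def read_annotation_db(phenotype_path, entity_path, annotation_path) -> AnnotationDB:
    """Read and validate the three-table database; schema violations raise
    :class:`SchemaError` listing the offending rows."""
    violations: List[str] = []
    db = AnnotationDB()

    header, rows = _read_rows(phenotype_path)
    if header[: len(_PHENOTYPE_HEADER)] != _PHENOTYPE_HEADER:
        raise SchemaError(
            [f"{phenotype_path}: header must start with {_PHENOTYPE_HEADER}, got {header}"]
        )
    for lineno, raw in rows:
        where = f"{phenotype_path}:{lineno}"
        if len(raw) < len(_PHENOTYPE_HEADER):
            violations.append(f"{where}: expected {len(_PHENOTYPE_HEADER)} columns")
            continue
        r_id = _int(raw[0], where, violations)
        p_id = _int(raw[1], where, violations)
        if r_id is None or p_id is None:
            continue
        db.phenotype_rows.append(
            PhenotypeRow(
                r_id=r_id,
                p_id=p_id,
                quality=raw[2].strip(),
                role=_opt(raw[3]),
                entity=raw[4].strip(),
                qualifier=_opt(raw[5]) if len(raw) > 5 else None,
            )
        )

    header, rows = _read_rows(entity_path)
    if not header or header[0] != "e_id":
        raise SchemaError([f"{entity_path}: header must start with 'e_id', got {header}"])
    attr_names = header[1:]
    for lineno, raw in rows:
        where = f"{entity_path}:{lineno}"
        e_id = _int(raw[0], where, violations)
        if e_id is None:
            continue
        attrs = tuple(
            (name, raw[i + 1].strip())
            for i, name in enumerate(attr_names)
            if i + 1 < len(raw) and raw[i + 1].strip() not in _NA_STRINGS
        )
        db.entity_rows.append(EntityRow(e_id=e_id, attributes=attrs))

    header, rows = _read_rows(annotation_path)
    if header[: len(_ANNOTATION_HEADER)] != _ANNOTATION_HEADER:
        raise SchemaError(
            [f"{annotation_path}: header must start with {_ANNOTATION_HEADER}, got {header}"]
        )
    for lineno, raw in rows:
        where = f"{annotation_path}:{lineno}"
        if len(raw) < 2:
            violations.append(f"{where}: expected at least 2 columns")
            continue
        e_id = _int(raw[0], where, violations)
        p_id = _int(raw[1], where, violations)
        if e_id is None or p_id is None:
            continue
        value_cell = _opt(raw[2]) if len(raw) > 2 else None
        unit_cell = _opt(raw[3]) if len(raw) > 3 else None
        value: Optional[Decimal] = None
        if value_cell is not None:
            try:
                value = Decimal(value_cell)
            except InvalidOperation:
                violations.append(f"{where}: not a decimal: {value_cell!r}")
                continue
        db.annotation_rows.append(
            AnnotationRow(e_id=e_id, p_id=p_id, measured_value=value, measuring_unit=unit_cell)
        )

    violations.extend(db.validate())
    if violations:
        raise SchemaError(violations)
    return db


def write_annotation_db(db: AnnotationDB, phenotype_path, entity_path, annotation_path) -> None:
    """Write the three tables back in the canonical TSV dialect."""
    def _dump(path, header: List[str], rows) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    _dump(
        phenotype_path,
        _PHENOTYPE_HEADER,
        [
            [r.r_id, r.p_id, r.quality, r.role or "", r.entity, r.qualifier or ""]
            for r in db.phenotype_rows
        ],
    )
    attr_names = sorted({name for row in db.entity_rows for name, _ in row.attributes})
    _dump(
        entity_path,
        ["e_id"] + attr_names,
        [
            [row.e_id] + [dict(row.attributes).get(name, "") for name in attr_names]
            for row in db.entity_rows
        ],
    )
    _dump(
        annotation_path,
        _ANNOTATION_HEADER,
        [
            [
                r.e_id,
                r.p_id,
                "" if r.measured_value is None else str(r.measured_value),
                r.measuring_unit or "",
            ]
            for r in db.annotation_rows
        ],
    )


# ---------------------------------------------------------------------------
# DB <-> profiles


def _group_key(stmts: Sequence[PhenotypeRow]) -> Tuple:
    return tuple((r.quality, r.role, r.entity, r.qualifier) for r in stmts)


def _term(curie: str, category: Category, taxonomy: Optional[Taxonomy]) -> Term:
    if taxonomy is not None:
        if curie not in taxonomy:
            raise UnknownTermError(f"database references undeclared term {curie}")
        declared = taxonomy.term(curie)
        return declared
    return Term(curie, category=category)


def db_to_profiles(
    db: AnnotationDB,
    *,
    taxonomy: Optional[Taxonomy] = None,
    relation_lookup: Optional[Mapping[str, Term]] = None,
) -> Dict[int, PhenotypeProfile]:
    """Convert an annotation database into one profile per annotated entity.

    Phenotype rows are grouped by ``p_id``: a group whose rows all have an
    empty role cell yields one simple statement per row; a group with role
    labels yields a single relational statement whose role list follows
    ``r_id`` order.  Groups mixing empty and nonempty roles, or differing in
    quality/qualifier, are schema errors.  ``relation_lookup`` optionally
    maps a relational quality's CURIE to its relator (relation) term so the
    resulting statements are usable under the relator-based-quality scheme.
    ``taxonomy``, when given, resolves CURIEs to declared terms (with labels
    and categories) and rejects undeclared ones.
    """
    groups: Dict[int, List[PhenotypeRow]] = {}
    for row in db.phenotype_rows:
        groups.setdefault(row.p_id, []).append(row)
    statements: Dict[int, List[EQStatement]] = {}
    for p_id, rows in sorted(groups.items()):
        rows = sorted(rows, key=lambda r: r.r_id)
        empties = [r.role is None for r in rows]
        if any(empties) and not all(empties):
            raise SchemaError(
                [f"p_id {p_id}: mixes simple (empty-role) and relational rows"]
            )
        if all(empties):
            stmts = []
            for r in rows:
                quality = _term(r.quality, Category.QUALITY, taxonomy)
                entity = _term(r.entity, Category.ENTITY, taxonomy)
                qualifier = (
                    _term(r.qualifier, Category.QUALIFIER, taxonomy) if r.qualifier else None
                )
                stmts.append(make_simple_statement(quality, entity, qualifier))
            statements[p_id] = stmts
        else:
            quality_curies = {r.quality for r in rows}
            if len(quality_curies) > 1:
                raise SchemaError(
                    [f"p_id {p_id}: relational rows carry different qualities "
                     f"{sorted(quality_curies)}"]
                )
            quality = _term(rows[0].quality, Category.QUALITY, taxonomy)
            qualifier = (
                _term(rows[0].qualifier, Category.QUALIFIER, taxonomy)
                if rows[0].qualifier
                else None
            )
            relation = None
            if relation_lookup is not None:
                relation = relation_lookup.get(quality.curie)
            roles = tuple(
                RoleAssignment(r.role, _term(r.entity, Category.ENTITY, taxonomy))
                for r in rows
            )
            statements[p_id] = [
                EQStatement(quality=quality, roles=roles, relation=relation, qualifier=qualifier)
            ]

    profiles: Dict[int, PhenotypeProfile] = {}
    by_entity: Dict[int, List[AnnotationRow]] = {}
    for row in db.annotation_rows:
        by_entity.setdefault(row.e_id, []).append(row)
    for e_id, rows in sorted(by_entity.items()):
        stmts: List[EQStatement] = []
        for row in sorted(rows, key=lambda r: r.p_id):
            measurement = (
                Measurement(row.measured_value, row.measuring_unit)
                if row.measured_value is not None
                else None
            )
            for s in statements[row.p_id]:
                if measurement is not None:
                    s = EQStatement(
                        quality=s.quality,
                        roles=s.roles,
                        relation=s.relation,
                        qualifier=s.qualifier,
                        measurement=measurement,
                    )
                stmts.append(s)
        profiles[e_id] = PhenotypeProfile(profile_id=str(e_id), statements=tuple(stmts))
    return profiles


def profiles_to_db(
    profiles: Mapping[int, PhenotypeProfile],
    *,
    entity_rows: Optional[Sequence[EntityRow]] = None,
) -> AnnotationDB:
    """Inverse of :func:`db_to_profiles` up to id renumbering.

    Statements identical up to measurement share one ``p_id`` across
    entities; measurements land on the (e_id, p_id) annotation row.
    ``entity_rows`` optionally carries the opaque entity table through a
    round trip (profiles themselves say nothing about entity attributes).
    """
    db = AnnotationDB()
    p_ids: Dict[Tuple, int] = {}
    next_r = 0
    for e_id in sorted(profiles):
        profile = profiles[e_id]
        for stmt in profile.statements:
            key = (
                stmt.quality.curie,
                tuple((ra.role_label, ra.filler.curie) for ra in stmt.roles),
                stmt.qualifier.curie if stmt.qualifier else None,
                stmt.is_simple,
            )
            if key not in p_ids:
                p_id = len(p_ids)
                p_ids[key] = p_id
                if stmt.is_simple:
                    rows = [(None, stmt.roles[0].filler.curie)]
                else:
                    rows = [(ra.role_label, ra.filler.curie) for ra in stmt.roles]
                for role, entity in rows:
                    db.phenotype_rows.append(
                        PhenotypeRow(
                            r_id=next_r,
                            p_id=p_id,
                            quality=stmt.quality.curie,
                            role=role,
                            entity=entity,
                            qualifier=stmt.qualifier.curie if stmt.qualifier else None,
                        )
                    )
                    next_r += 1
            db.annotation_rows.append(
                AnnotationRow(
                    e_id=e_id,
                    p_id=p_ids[key],
                    measured_value=stmt.measurement.value if stmt.measurement else None,
                    measuring_unit=stmt.measurement.unit if stmt.measurement else None,
                )
            )
    if entity_rows is not None:
        db.entity_rows = list(entity_rows)
    else:
        db.entity_rows = [EntityRow(e_id=e) for e in sorted(profiles)]
    problems = db.validate()
    if problems:
        raise SchemaError(problems)
    return db


def db_equal_up_to_ids(a: AnnotationDB, b: AnnotationDB) -> bool:
    """Equality up to row ordering and r_id/p_id renumbering.

    Phenotype groups are compared by content; annotation rows by (e_id,
    group content, measurement); entity rows by (e_id, attributes).
    """
    def canon(db: AnnotationDB):
        groups: Dict[int, List[PhenotypeRow]] = {}
        for row in db.phenotype_rows:
            groups.setdefault(row.p_id, []).append(row)
        content = {
            p_id: _group_key(sorted(rows, key=lambda r: r.r_id))
            for p_id, rows in groups.items()
        }
        pheno = sorted(content.values())
        annot = sorted(
            (r.e_id, content.get(r.p_id), str(r.measured_value), r.measuring_unit)
            for r in db.annotation_rows
        )
        ents = sorted((r.e_id, tuple(sorted(r.attributes))) for r in db.entity_rows)
        return pheno, annot, ents

    return canon(a) == canon(b)


# ---------------------------------------------------------------------------
# Taxonomy TSV

_TAXONOMY_HEADER = ["record", "field_1", "field_2", "field_3"]


def read_taxonomy(path) -> Taxonomy:
    """Read a taxonomy TSV (record kinds ``term``/``subclass``/``disjoint``)."""
    header, rows = _read_rows(path)
    if header[0] != "record":
        raise SchemaError([f"{path}: header must start with 'record', got {header}"])
    terms: List[Term] = []
    edges: List[Tuple[str, str]] = []
    pairs: List[Tuple[str, str]] = []
    violations: List[str] = []
    for lineno, raw in rows:
        kind = raw[0].strip()
        where = f"{path}:{lineno}"
        if kind == "term":
            if len(raw) < 4:
                violations.append(f"{where}: term rows need curie, label, category")
                continue
            label = _opt(raw[2])
            try:
                terms.append(Term(raw[1].strip(), label=label, category=Category(raw[3].strip())))
            except ValueError as exc:
                violations.append(f"{where}: {exc}")
        elif kind == "subclass":
            if len(raw) < 3:
                violations.append(f"{where}: subclass rows need child, parent")
                continue
            edges.append((raw[1].strip(), raw[2].strip()))
        elif kind == "disjoint":
            if len(raw) < 3:
                violations.append(f"{where}: disjoint rows need two curies")
                continue
            pairs.append((raw[1].strip(), raw[2].strip()))
        else:
            violations.append(f"{where}: unknown record kind {kind!r}")
    if violations:
        raise SchemaError(violations)
    return Taxonomy(terms, edges, pairs)


def write_taxonomy(tax: Taxonomy, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n")
        writer.writerow(_TAXONOMY_HEADER)
        for curie in sorted(tax.terms):
            t = tax.term(curie)
            writer.writerow(["term", t.curie, t.label or "", t.category.value])
        for child, parent in sorted(tax.subclass_edges):
            writer.writerow(["subclass", child, parent, ""])
        for pair in sorted(tuple(sorted(p)) for p in tax.disjoint_pairs):
            writer.writerow(["disjoint", pair[0], pair[1], ""])


# ---------------------------------------------------------------------------
# Instance graph TSV

_GRAPH_HEADER = ["record", "field_1", "field_2", "field_3"]


def read_instance_graph(path) -> InstanceGraph:
    """Read an instance graph TSV (record kinds ``node``/``edge``)."""
    header, rows = _read_rows(path)
    if header[0] != "record":
        raise SchemaError([f"{path}: header must start with 'record', got {header}"])
    g = InstanceGraph()
    deferred_edges: List[Tuple[str, str, str]] = []
    violations: List[str] = []
    for lineno, raw in rows:
        kind = raw[0].strip()
        where = f"{path}:{lineno}"
        if kind == "node":
            if len(raw) < 3:
                violations.append(f"{where}: node rows need id, type_curie")
                continue
            g.add_node(raw[1].strip(), Term(raw[2].strip()))
        elif kind == "edge":
            if len(raw) < 4:
                violations.append(f"{where}: edge rows need source, relation, target")
                continue
            deferred_edges.append((raw[1].strip(), raw[2].strip(), raw[3].strip()))
        else:
            violations.append(f"{where}: unknown record kind {kind!r}")
    if violations:
        raise SchemaError(violations)
    for source, relation, target in deferred_edges:
        g.add_edge(source, relation, target)
    return g


def write_instance_graph(g: InstanceGraph, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n")
        writer.writerow(_GRAPH_HEADER)
        for node_id, term in sorted(g.nodes.items()):
            writer.writerow(["node", node_id, term.curie, ""])
        for source, relation, target in sorted(g.edges):
            writer.writerow(["edge", source, relation, target])


# Emitted-ontology round trip (thin aliases so the io surface is complete).
parse_owl_subset = parse_ontology
write_owl_subset = write_ontology
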