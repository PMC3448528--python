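"""Worked examples and seeded synthetic inputs.

:func:`make_reference_bundle` builds, in code, the running examples every
other module is exercised against: the red-eye / short-tail qualities with
their disjoint quality families, the iron-in-spleen relational quality with
its concentrated/concentrator role base, the symmetric eye-distance
relation, the three-table sample annotation database, and two instance
graphs for hasPheno justification.  No ontology download is involved: the
CURIEs are real-looking PATO/MA/CHEBI identifiers but the hierarchies are
minimal stubs.

:func:`generate_random_profiles` is the seeded generator used by the
property-test suites: shallow quality forests partitioned into mutually
disjoint families, a pool of entity stubs, and a mix of simple and
relational statements drawn from generated role bases.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Dict, List, Mapping, Tuple

from .errors import ConfigError
from .io import AnnotationDB, AnnotationRow, EntityRow, PhenotypeRow
from .justify import InstanceGraph
from .model import (
    And,
    Atom,
    Category,
    ClassExpr,
    EQStatement,
    INHERES_IN,
    PhenotypeProfile,
    RelationSpec,
    RoleAssignment,
    Some,
    Taxonomy,
    Term,
    TOWARDS,
    make_relational_statement,
    make_simple_statement,
)

__all__ = [
    "FixtureBundle", "make_reference_bundle",
    "GeneratorConfig", "generate_random_profiles",
    "generate_random_expressions",
]


@dataclass
class FixtureBundle:
    """Everything the worked examples need, internally consistent."""

    taxonomy: Taxonomy
    relation_specs: List[RelationSpec]
    sample_db: AnnotationDB
    instance_graphs: Dict[str, InstanceGraph]
    relation_lookup: Dict[str, Term]
    terms_by_label: Dict[str, Term]

    def term(self, label: str) -> Term:
        return self.terms_by_label[label]


def make_reference_bundle() -> FixtureBundle:
    """Build the worked-example fixture bundle."""
    q = Category.QUALITY
    e = Category.ENTITY
    terms = [
        # quality families; color/size/morphology are pairwise disjoint roots
        Term("PATO:0000014", "color", q),
        Term("PATO:0000117", "size", q),
        Term("PATO:0000051", "morphology", q),
        Term("PATO:0000322", "red", q),
        Term("PATO:0000574", "short", q),
        Term("PATO:0000033", "concentration of", q),
        Term("PATO:0001162", "increased concentration", q),
        Term("PATO:0000040", "distance", q),
        Term("PATO:0000460", "abnormal", Category.QUALIFIER),
        # entities
        Term("MA:000261", "eye", e),
        Term("MA:0000008", "tail", e),
        Term("MA:0000141", "spleen", e),
        Term("MA:0002405", "organism", e),
        Term("MA:0001800", "left eye", e),
        Term("MA:0001801", "right eye", e),
        Term("CHEBI:18248", "iron", e),
        # relator relations
        Term("REL:isConcentratedIn", "is concentrated in", Category.RELATION),
        Term("REL:isDistantFrom", "is distant from", Category.RELATION),
    ]
    taxonomy = Taxonomy(
        terms,
        subclass_edges=[
            ("PATO:0000322", "PATO:0000014"),  # red ⊑ color
            ("PATO:0000574", "PATO:0000117"),  # short ⊑ size
            ("PATO:0001162", "PATO:0000033"),  # increased conc. ⊑ concentration of
        ],
        disjoint_pairs=[
            ("PATO:0000014", "PATO:0000117"),
            ("PATO:0000014", "PATO:0000051"),
            ("PATO:0000117", "PATO:0000051"),
        ],
    )
    by_label = {t.label: t for t in terms}

    relation_specs = [
        RelationSpec(
            relation=by_label["is concentrated in"],
            role_base=("concentrated", "concentrator"),
            min_arity=2,
            max_arity=2,
        ),
        # symmetric relation: one role category, multiply instantiable
        RelationSpec(
            relation=by_label["is distant from"],
            role_base=("relatum",),
            min_arity=2,
            max_arity=None,
            allow_repeats=True,
        ),
    ]
    relation_lookup = {
        "PATO:0000033": by_label["is concentrated in"],
        "PATO:0001162": by_label["is concentrated in"],
    }

    sample_db = AnnotationDB(
        phenotype_rows=[
            PhenotypeRow(0, 0, "PATO:0000322", None, "MA:000261", None),
            PhenotypeRow(1, 1, "PATO:0000033", "concentrator", "MA:0000141", "PATO:0000460"),
            PhenotypeRow(2, 1, "PATO:0000033", "concentrated", "CHEBI:18248", "PATO:0000460"),
            PhenotypeRow(3, 2, "PATO:0001162", "concentrator", "MA:0000141", None),
            PhenotypeRow(4, 2, "PATO:0001162", "concentrated", "CHEBI:18248", None),
        ],
        entity_rows=[EntityRow(0), EntityRow(1), EntityRow(2), EntityRow(3)],
        annotation_rows=[
            AnnotationRow(0, 0, None, None),
            AnnotationRow(0, 1, Decimal(5), "mg/kg"),
            AnnotationRow(1, 2, None, None),
            AnnotationRow(2, 2, None, None),
        ],
    )

    # organism O — eye E — red R: the hasPheno(O, R) link is justified by
    # R –inheres-in→ E –part-of→ O; a second red instance is left isolated.
    oer = InstanceGraph()
    oer.add_node("organism-1", by_label["organism"])
    oer.add_node("eye-1", by_label["eye"])
    oer.add_node("red-1", by_label["red"])
    oer.add_node("red-2", by_label["red"])
    oer.add_edge("red-1", "inheres-in", "eye-1")
    oer.add_edge("eye-1", "part-of", "organism-1")
    oer.add_edge("organism-1", "hasPheno", "red-1")
    oer.add_edge("organism-1", "hasPheno", "red-2")

    # relator reading of iron concentration in the spleen: the CO quality
    # inheres in a CI relator whose roles are played by iron and spleen.
    relator = InstanceGraph()
    relator.add_node("iron-1", by_label["iron"])
    relator.add_node("spleen-1", by_label["spleen"])
    relator.add_node("organism-1", by_label["organism"])
    relator.add_node("ci-relator-1", by_label["is concentrated in"])
    relator.add_node("concentrated-role-1", Term("GEN:Concentrated", "concentrated", Category.ROLE))
    relator.add_node("concentrator-role-1", Term("GEN:Concentrator", "concentrator", Category.ROLE))
    relator.add_node("co-quality-1", by_label["concentration of"])
    relator.add_edge("iron-1", "plays", "concentrated-role-1")
    relator.add_edge("spleen-1", "plays", "concentrator-role-1")
    relator.add_edge("concentrated-role-1", "role-of", "ci-relator-1")
    relator.add_edge("concentrator-role-1", "role-of", "ci-relator-1")
    relator.add_edge("co-quality-1", "inheres-in", "ci-relator-1")
    relator.add_edge("spleen-1", "part-of", "organism-1")
    relator.add_edge("organism-1", "hasPheno", "co-quality-1")

    return FixtureBundle(
        taxonomy=taxonomy,
        relation_specs=relation_specs,
        sample_db=sample_db,
        instance_graphs={"organism-eye-red": oer, "iron-spleen-relator": relator},
        relation_lookup=relation_lookup,
        terms_by_label=by_label,
    )


# ---------------------------------------------------------------------------
# Seeded random generator


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-profile generator.

    Defaults describe a small but structured corpus: a dozen entity stubs,
    nine qualities in three mutually disjoint families (mirroring the
    color/size/morphology split), thirty distinct statements of which
    roughly 40% are relational, mostly binary with occasional ternary
    relations — the shapes annotation databases actually contain.
    """

    seed: int = 0
    n_entities: int = 12
    n_qualities: int = 9
    n_statements: int = 30
    relational_fraction: float = 0.4
    arity_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 3.0, 3: 1.0}
    )
    disjoint_quality_families: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.relational_fraction <= 1.0:
            raise ConfigError("relational_fraction must be in [0, 1]")
        dist = dict(self.arity_distribution)
        if not dist or any(w < 0 for w in dist.values()) or not any(dist.values()):
            raise ConfigError("arity_distribution needs nonnegative, not-all-zero weights")
        if any(a < 1 for a in dist):
            raise ConfigError("arities must be >= 1")
        if self.disjoint_quality_families < 1:
            raise ConfigError("need at least one quality family")
        if self.n_qualities < self.disjoint_quality_families:
            raise ConfigError("need at least one quality per family")
        if min(self.n_entities, self.n_statements) < 1:
            raise ConfigError("n_entities and n_statements must be >= 1")
        if self.relational_fraction == 0.0 and self.n_statements > (
            self.n_qualities * self.n_entities
        ):
            raise ConfigError(
                "n_statements exceeds the number of distinct simple statements"
            )


def generate_random_profiles(
    cfg: GeneratorConfig,
) -> Tuple[Taxonomy, List[PhenotypeProfile], List[RelationSpec]]:
    """Deterministically generate (taxonomy, profiles, relation specs).

    Quality stubs are partitioned into ``disjoint_quality_families``
    mutually disjoint shallow subtrees (forest depth <= 3, keeping the
    brute-force oracle tractable); every relational statement conforms to
    its generated :class:`RelationSpec` and carries the relation term, so
    all role-based schemes — including relator-based-quality — apply.
    """
    rng = random.Random(cfg.seed)
    entities = [
        Term(f"ENT:{i:04d}", f"entity-{i}", Category.ENTITY) for i in range(cfg.n_entities)
    ]
    roots = [
        Term(f"QUAL:F{j}", f"family-{j}", Category.QUALITY)
        for j in range(cfg.disjoint_quality_families)
    ]
    qualities = [
        Term(f"QUAL:{i:04d}", f"quality-{i}", Category.QUALITY) for i in range(cfg.n_qualities)
    ]
    edges = [
        (qual.curie, roots[i % len(roots)].curie) for i, qual in enumerate(qualities)
    ]
    pairs = [
        (roots[i].curie, roots[j].curie)
        for i in range(len(roots))
        for j in range(i + 1, len(roots))
    ]

    arities = sorted(a for a, w in dict(cfg.arity_distribution).items() if w > 0)
    weights = [dict(cfg.arity_distribution)[a] for a in arities]
    specs: List[RelationSpec] = []
    spec_by_arity: Dict[int, RelationSpec] = {}
    relation_terms: List[Term] = []
    for a in arities:
        letters = "ABCDEFGHIJ"
        rel = Term(f"REL:rel{a}ary", f"relation-{a}ary", Category.RELATION)
        relation_terms.append(rel)
        spec = RelationSpec(
            relation=rel,
            role_base=tuple(f"rel{a}Arg{letters[k]}" for k in range(a)),
            min_arity=a,
            max_arity=a,
        )
        specs.append(spec)
        spec_by_arity[a] = spec

    taxonomy = Taxonomy(entities + roots + qualities + relation_terms, edges, pairs)

    statements: List[EQStatement] = []
    seen = set()
    attempts = 0
    while len(statements) < cfg.n_statements:
        attempts += 1
        if attempts > 200 * cfg.n_statements:
            raise ConfigError("cannot draw enough distinct statements; config infeasible")
        quality = rng.choice(qualities)
        if rng.random() < cfg.relational_fraction:
            arity = rng.choices(arities, weights=weights, k=1)[0]
            spec = spec_by_arity[arity]
            assignments = [
                RoleAssignment(label, rng.choice(entities)) for label in spec.role_base
            ]
            stmt = make_relational_statement(
                quality, assignments, relation=spec.relation, spec=spec
            )
        else:
            stmt = make_simple_statement(quality, rng.choice(entities))
        key = (
            stmt.quality.curie,
            tuple((ra.role_label, ra.filler.curie) for ra in stmt.roles),
        )
        if key in seen:
            continue
        seen.add(key)
        statements.append(stmt)

    profiles: List[PhenotypeProfile] = []
    i = 0
    while i < len(statements):
        k = min(rng.randint(1, 3), len(statements) - i)
        profiles.append(
            PhenotypeProfile(
                profile_id=f"P{len(profiles):03d}",
                statements=tuple(statements[i : i + k]),
            )
        )
        i += k
    return taxonomy, profiles, specs


def generate_random_expressions(
    seed: int,
    n_expressions: int,
) -> Tuple[Taxonomy, List[ClassExpr]]:
    """Seeded suite of small class expressions for reasoner validation.

    The taxonomy is two mutually disjoint quality families (root plus two
    leaves each) and two entity stubs; expressions have depth <= 1, at most
    three conjuncts and at most two existential restrictions, so every
    satisfiability or subsumption witness fits into a three-node tree model
    and :func:`eqowl.reason.small_model_oracle` is exhaustive at its default
    domain bound.
    """
    rng = random.Random(seed)
    terms = [
        Term("QUAL:FA", "family-a", Category.QUALITY),
        Term("QUAL:FB", "family-b", Category.QUALITY),
        Term("QUAL:a1", None, Category.QUALITY),
        Term("QUAL:a2", None, Category.QUALITY),
        Term("QUAL:b1", None, Category.QUALITY),
        Term("QUAL:b2", None, Category.QUALITY),
        Term("ENT:e1", None, Category.ENTITY),
        Term("ENT:e2", None, Category.ENTITY),
    ]
    tax = Taxonomy(
        terms,
        [
            ("QUAL:a1", "QUAL:FA"),
            ("QUAL:a2", "QUAL:FA"),
            ("QUAL:b1", "QUAL:FB"),
            ("QUAL:b2", "QUAL:FB"),
        ],
        [("QUAL:FA", "QUAL:FB")],
    )
    atoms = [Atom(t) for t in terms]
    props = [INHERES_IN, TOWARDS]

    def filler() -> ClassExpr:
        if rng.random() < 0.5:
            return rng.choice(atoms)
        return And((rng.choice(atoms), rng.choice(atoms)))

    def expression() -> ClassExpr:
        n_some = rng.randint(0, 2)
        parts: List[ClassExpr] = [
            Some(rng.choice(props), filler()) for _ in range(n_some)
        ]
        parts.extend(rng.choice(atoms) for _ in range(rng.randint(1, 3 - n_some) if n_some < 3 else 0))
        rng.shuffle(parts)
        if len(parts) == 1:
            return parts[0]
        return And(tuple(parts))

    return tax, [expression() for _ in range(n_expressions)]
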