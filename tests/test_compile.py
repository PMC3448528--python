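"""Compiler tests: the five schemes, composition modes, emission, vocabulary."""

import pytest

from eqowl.compile import (
    ALL_SCHEMES,
    CLASSIC_EQ,
    ENTITY_FOCUSED,
    RELATOR_RC,
    RELATOR_RP,
    ROLES_AS_CLASSES,
    ROLES_AS_PROPERTIES,
    Scheme,
    SchemeKind,
    compile_statement,
    compose_profile,
    emit_ontology,
    role_property,
    vocab_inventory,
)
from eqowl.errors import (
    MissingRelatorError,
    NameCollisionError,
    UnknownTermError,
    UnsupportedArityError,
    UnsupportedShapeError,
)
from eqowl.model import (
    HAS_PHENO,
    HAS_QUALITY,
    HAS_ROLE,
    INHERES_IN,
    PLAYED_BY,
    Category,
    PhenotypeProfile,
    RoleAssignment,
    Some,
    Term,
    make_relational_statement,
    make_simple_statement,
    iter_props,
)
from eqowl.owlfs import write_ontology
from eqowl.reason import normalize


def canon(expr):
    return normalize(expr).text


# ---------------------------------------------------------------------------
# compile_statement: the five patterns


def test_classic_simple_is_quality_with_inherence(red_eye):
    expr = compile_statement(red_eye, CLASSIC_EQ)
    assert canon(expr) == "and(PATO:0000322,some(fixed:inheresIn,MA:000261))"


def test_entity_focused_centers_on_the_bearer(red_eye):
    expr = compile_statement(red_eye, ENTITY_FOCUSED)
    assert canon(expr) == "and(MA:000261,some(fixed:hasQuality,PATO:0000322))"


def test_classic_relational_uses_inherence_and_towards(iron_spleen):
    expr = compile_statement(iron_spleen, CLASSIC_EQ)
    assert canon(expr) == (
        "and(PATO:0000033,"
        "some(fixed:inheresIn,CHEBI:18248),"
        "some(fixed:towards,MA:0000141))"
    )


def test_classic_slot_maps_swap_the_argument_assignment(iron_spleen):
    std = compile_statement(iron_spleen, CLASSIC_EQ, slot_map="standard")
    rev = compile_statement(iron_spleen, CLASSIC_EQ, slot_map="reversed")
    assert canon(std) != canon(rev)
    assert canon(rev) == (
        "and(PATO:0000033,"
        "some(fixed:inheresIn,MA:0000141),"
        "some(fixed:towards,CHEBI:18248))"
    )


def test_classic_relational_logs_ambiguity_warning(iron_spleen, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="eqowl.compile"):
        compile_statement(iron_spleen, CLASSIC_EQ)
    assert any("ambiguous" in rec.message for rec in caplog.records)


def test_roles_as_properties_generates_one_property_per_role(iron_spleen):
    expr = compile_statement(iron_spleen, ROLES_AS_PROPERTIES)
    assert canon(expr) == (
        "and(REL:isConcentratedIn,"
        "some(generated:concentrated,CHEBI:18248),"
        "some(generated:concentrator,MA:0000141))"
    )


def test_roles_as_classes_reifies_role_categories(iron_spleen):
    expr = compile_statement(iron_spleen, ROLES_AS_CLASSES)
    assert canon(expr) == (
        "and(REL:isConcentratedIn,"
        "some(fixed:hasRole,and(GEN:Concentrated,some(fixed:playedBy,CHEBI:18248))),"
        "some(fixed:hasRole,and(GEN:Concentrator,some(fixed:playedBy,MA:0000141))))"
    )


def test_relator_scheme_nests_relation_under_inherence(iron_spleen):
    expr = compile_statement(iron_spleen, RELATOR_RP)
    assert canon(expr) == (
        "and(PATO:0000033,some(fixed:inheresIn,"
        "and(REL:isConcentratedIn,"
        "some(generated:concentrated,CHEBI:18248),"
        "some(generated:concentrator,MA:0000141))))"
    )


def test_relator_scheme_with_role_classes(iron_spleen):
    expr = compile_statement(iron_spleen, RELATOR_RC)
    assert canon(expr) == (
        "and(PATO:0000033,some(fixed:inheresIn,"
        "and(REL:isConcentratedIn,"
        "some(fixed:hasRole,and(GEN:Concentrated,some(fixed:playedBy,CHEBI:18248))),"
        "some(fixed:hasRole,and(GEN:Concentrator,some(fixed:playedBy,MA:0000141))))))"
    )


def test_head_atom_points_to_quality_when_no_relation_term(bundle):
    stmt = make_relational_statement(
        bundle.term("concentration of"),
        [
            RoleAssignment("concentrated", bundle.term("iron")),
            RoleAssignment("concentrator", bundle.term("spleen")),
        ],
    )
    expr = compile_statement(stmt, ROLES_AS_PROPERTIES)
    assert canon(expr).startswith("and(PATO:0000033,")


def test_qualifier_becomes_extra_conjunct(bundle):
    stmt = make_simple_statement(
        bundle.term("red"), bundle.term("eye"), qualifier=bundle.term("abnormal")
    )
    assert canon(compile_statement(stmt, CLASSIC_EQ)) == (
        "and(PATO:0000322,PATO:0000460,some(fixed:inheresIn,MA:000261))"
    )
    # entity-focused keeps the qualifier with the quality, not the entity
    assert canon(compile_statement(stmt, ENTITY_FOCUSED)) == (
        "and(MA:000261,some(fixed:hasQuality,and(PATO:0000322,PATO:0000460)))"
    )


def test_symmetric_relation_repeats_role_vocabulary(eye_distance):
    rp = compile_statement(eye_distance, ROLES_AS_PROPERTIES)
    props = [p for p in iter_props(rp) if p.kind == "generated"]
    assert len(props) == 2 and len(set(props)) == 1  # one property, used twice
    rc = compile_statement(eye_distance, ROLES_AS_CLASSES)
    has_role_conjuncts = [c for c in rc.conjuncts if isinstance(c, Some) and c.prop == HAS_ROLE]
    assert len(has_role_conjuncts) == 2
    role_atoms = {canon(c.filler.conjuncts[0]) for c in has_role_conjuncts}
    assert role_atoms == {"GEN:Relatum"}  # single role class, instantiated twice


# ---------------------------------------------------------------------------
# Scheme error surface


def test_classic_rejects_arity_three(bundle):
    ternary = make_relational_statement(
        bundle.term("concentration of"),
        [
            RoleAssignment("a", bundle.term("iron")),
            RoleAssignment("b", bundle.term("spleen")),
            RoleAssignment("c", bundle.term("organism")),
        ],
    )
    with pytest.raises(UnsupportedArityError):
        compile_statement(ternary, CLASSIC_EQ)
    for scheme in (ROLES_AS_PROPERTIES, ROLES_AS_CLASSES):
        compile_statement(ternary, scheme)  # must not raise


def test_entity_focused_rejects_relational(iron_spleen):
    with pytest.raises(UnsupportedShapeError):
        compile_statement(iron_spleen, ENTITY_FOCUSED)


def test_relator_scheme_requires_relation_term(bundle):
    stmt = make_relational_statement(
        bundle.term("concentration of"),
        [
            RoleAssignment("concentrated", bundle.term("iron")),
            RoleAssignment("concentrator", bundle.term("spleen")),
        ],
    )
    with pytest.raises(MissingRelatorError):
        compile_statement(stmt, RELATOR_RP)


def test_generated_property_cannot_shadow_fixed_names():
    with pytest.raises(NameCollisionError):
        role_property("inheres in")


def test_sub_scheme_only_for_relator():
    with pytest.raises(ValueError):
        Scheme(SchemeKind.CLASSIC_EQ, SchemeKind.ROLES_AS_CLASSES)


# ---------------------------------------------------------------------------
# Profile composition


def test_naive_composition_flattens_intersections(red_short_profile):
    expr = compose_profile(red_short_profile, CLASSIC_EQ, "naive")
    assert canon(expr) == (
        "and(PATO:0000322,PATO:0000574,"
        "some(fixed:inheresIn,MA:0000008),some(fixed:inheresIn,MA:000261))"
    )


def test_haspheno_composition_encapsulates_each_statement(red_short_profile):
    expr = compose_profile(red_short_profile, CLASSIC_EQ, "haspheno")
    assert canon(expr) == (
        "and(some(fixed:hasPheno,and(PATO:0000322,some(fixed:inheresIn,MA:000261))),"
        "some(fixed:hasPheno,and(PATO:0000574,some(fixed:inheresIn,MA:0000008))))"
    )


def test_single_statement_composes_to_itself(red_eye):
    profile = PhenotypeProfile("solo", (red_eye,))
    bare = compose_profile(profile, CLASSIC_EQ, "naive")
    assert bare == compile_statement(red_eye, CLASSIC_EQ)
    wrapped = compose_profile(profile, CLASSIC_EQ, "haspheno")
    assert wrapped == Some(HAS_PHENO, compile_statement(red_eye, CLASSIC_EQ))


# ---------------------------------------------------------------------------
# Emission


def test_emit_declares_only_used_properties(red_eye, tax):
    profile = PhenotypeProfile("red-eye", (red_eye,))
    ont = emit_ontology([profile], CLASSIC_EQ, "naive", tax)
    assert len(ont.named_class_definitions) == 1
    assert ont.declared_object_properties == frozenset({INHERES_IN})


def test_emit_empty_input_keeps_taxonomy_axioms(tax):
    ont = emit_ontology([], CLASSIC_EQ, "naive", tax)
    assert not ont.named_class_definitions
    assert set(ont.subclass_axioms) == set(tax.subclass_edges)
    assert len(ont.disjoint_axioms) == len(tax.disjoint_pairs)


def test_emit_roles_as_classes_declares_generated_vocabulary(iron_spleen, tax):
    profile = PhenotypeProfile("iron-spleen", (iron_spleen,))
    ont = emit_ontology([profile], ROLES_AS_CLASSES, "haspheno", tax)
    assert {HAS_ROLE, PLAYED_BY, HAS_PHENO} <= ont.declared_object_properties
    assert {"GEN:Concentrated", "GEN:Concentrator"} <= ont.declared_classes


def test_emit_rejects_undeclared_terms(red_eye):
    from eqowl.model import Taxonomy

    with pytest.raises(UnknownTermError):
        emit_ontology(
            [PhenotypeProfile("p", (red_eye,))], CLASSIC_EQ, "naive", Taxonomy()
        )


def test_emit_rejects_generated_name_collisions(iron_spleen, tax):
    clashing = tax.with_terms([Term("GEN:Concentrated", "already taken", Category.ENTITY)])
    with pytest.raises(NameCollisionError):
        emit_ontology(
            [PhenotypeProfile("p", (iron_spleen,))], ROLES_AS_CLASSES, "naive", clashing
        )


def test_emission_is_byte_deterministic(bundle, red_short_profile, iron_spleen):
    profiles = [red_short_profile, PhenotypeProfile("iron", (iron_spleen,))]
    texts = {
        write_ontology(emit_ontology(profiles, RELATOR_RC, "haspheno", bundle.taxonomy))
        for _ in range(3)
    }
    assert len(texts) == 1


# ---------------------------------------------------------------------------
# Vocabulary accounting


def _nary_statement(bundle, arity, with_relation=False):
    labels = ["argA", "argB", "argC", "argD", "argE"][:arity]
    entities = [bundle.term("iron"), bundle.term("spleen"), bundle.term("organism"),
                bundle.term("eye"), bundle.term("tail")]
    return make_relational_statement(
        bundle.term("concentration of"),
        [RoleAssignment(lbl, ent) for lbl, ent in zip(labels, entities)],
        relation=bundle.term("is concentrated in") if with_relation else None,
    )


@pytest.mark.parametrize("arity", [2, 3, 4, 5])
def test_vocab_counts_scale_with_arity(bundle, arity):
    stmt = _nary_statement(bundle, arity)
    rp = vocab_inventory(ROLES_AS_PROPERTIES, stmt)
    assert (rp.new_classes, rp.new_object_properties) == (0, arity)
    rc = vocab_inventory(ROLES_AS_CLASSES, stmt)
    assert (rc.new_classes, rc.new_object_properties) == (arity, 2)
    rel = vocab_inventory(RELATOR_RP, _nary_statement(bundle, arity, with_relation=True))
    assert (rel.new_classes, rel.new_object_properties) == (0, arity + 1)


def test_vocab_counts_for_classic_relational(iron_spleen):
    inv = vocab_inventory(CLASSIC_EQ, iron_spleen)
    assert (inv.new_classes, inv.new_object_properties) == (0, 2)
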