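"""Reasoner tests: normalization, satisfiability, subsumption, permutation
diagnostics, and exact agreement with the brute-force small-model oracle."""

import itertools
import random

import pytest

from eqowl.compile import CLASSIC_EQ, ROLES_AS_CLASSES, ROLES_AS_PROPERTIES, compose_profile
from eqowl.errors import SizeLimitError, UnknownTermError
from eqowl.fixtures import generate_random_expressions
from eqowl.model import (
    And,
    Atom,
    HAS_PHENO,
    INHERES_IN,
    PhenotypeProfile,
    Some,
    make_simple_statement,
)
from eqowl.reason import (
    TreeModel,
    diagnose_permutations,
    equivalent,
    evaluate,
    is_satisfiable,
    normalize,
    small_model_oracle,
    subsumes,
)


@pytest.fixture(scope="module")
def suite():
    """Seeded random expression suite with its (oracle-tractable) taxonomy."""
    return generate_random_expressions(seed=20_001, n_expressions=150)


def atom(bundle, label):
    return Atom(bundle.term(label))


# ---------------------------------------------------------------------------
# Normalization


def test_normalize_erases_grouping_and_order(bundle):
    red, short = atom(bundle, "red"), atom(bundle, "short")
    eye, tail = atom(bundle, "eye"), atom(bundle, "tail")
    crossed = And(
        (And((red, Some(INHERES_IN, tail))), And((short, Some(INHERES_IN, eye))))
    )
    straight = And(
        (And((red, Some(INHERES_IN, eye))), And((short, Some(INHERES_IN, tail))))
    )
    # intersection is commutative/associative: both pairings share one form
    assert normalize(crossed).text == normalize(straight).text


def test_normalize_deduplicates_conjuncts(bundle):
    red = atom(bundle, "red")
    assert normalize(And((red, red))).expr == red


def test_normalize_is_idempotent_on_random_expressions(suite):
    _, exprs = suite
    for expr in exprs:
        once = normalize(expr)
        assert normalize(once.expr).text == once.text


def test_normalize_is_invariant_under_conjunct_shuffles(suite):
    rng = random.Random(7)
    _, exprs = suite
    for expr in exprs:
        if not isinstance(expr, And):
            continue
        shuffled = list(expr.conjuncts)
        rng.shuffle(shuffled)
        assert normalize(And(tuple(shuffled))).text == normalize(expr).text


# ---------------------------------------------------------------------------
# Satisfiability


def test_naive_red_short_composition_is_unsatisfiable(red_short_profile, tax):
    expr = compose_profile(red_short_profile, CLASSIC_EQ, "naive")
    report = is_satisfiable(expr, tax)
    assert not report.satisfiable
    a, b, path = report.clash
    assert {a, b} == {"PATO:0000322", "PATO:0000574"}
    assert path == ()


def test_haspheno_composition_is_satisfiable(red_short_profile, tax):
    expr = compose_profile(red_short_profile, CLASSIC_EQ, "haspheno")
    assert is_satisfiable(expr, tax).satisfiable


def test_unsatisfiable_filler_propagates_upward(bundle, tax):
    expr = Some(HAS_PHENO, And((atom(bundle, "red"), atom(bundle, "short"))))
    report = is_satisfiable(expr, tax)
    assert not report.satisfiable
    assert report.clash[2] == ("hasPheno",)


def test_hidden_family_clash_via_taxonomy(bundle, tax):
    # a red eye asserted to also be a morphology quality: color and
    # morphology roots are disjoint, so the class is contradictory
    expr = And(
        (atom(bundle, "red"), Some(INHERES_IN, atom(bundle, "eye")), atom(bundle, "morphology"))
    )
    assert not is_satisfiable(expr, tax).satisfiable


def test_satisfiability_requires_declared_atoms(tax):
    from eqowl.model import Term

    with pytest.raises(UnknownTermError):
        is_satisfiable(Atom(Term("NOPE:1")), tax)


# ---------------------------------------------------------------------------
# Subsumption / equivalence


def test_conjunct_removal_yields_subsumer(bundle, tax):
    whole = And((atom(bundle, "red"), Some(INHERES_IN, atom(bundle, "eye"))))
    assert subsumes(Some(INHERES_IN, atom(bundle, "eye")), whole, tax)
    assert not subsumes(whole, Some(INHERES_IN, atom(bundle, "eye")), tax)


def test_atomic_subsumption_lifts_through_structure(bundle, tax):
    sup = And((atom(bundle, "color"), Some(INHERES_IN, atom(bundle, "eye"))))
    sub = And((atom(bundle, "red"), Some(INHERES_IN, atom(bundle, "eye"))))
    assert subsumes(sup, sub, tax)
    assert not subsumes(sub, sup, tax)


def test_mismatched_fillers_block_subsumption(bundle, tax):
    a = And((atom(bundle, "red"), Some(INHERES_IN, atom(bundle, "tail"))))
    b = And((atom(bundle, "red"), Some(INHERES_IN, atom(bundle, "eye"))))
    assert not subsumes(a, b, tax)


def test_unsatisfiable_class_is_subsumed_by_everything(bundle, tax):
    bottom = And((atom(bundle, "red"), atom(bundle, "short")))
    assert subsumes(atom(bundle, "tail"), bottom, tax)


def test_existential_monotonicity(bundle, tax):
    # X ⊑ Y implies ∃r.X ⊑ ∃r.Y
    x = And((atom(bundle, "red"), atom(bundle, "distance")))
    y = atom(bundle, "red")
    assert subsumes(Some(INHERES_IN, y), Some(INHERES_IN, x), tax)


def test_subsumption_reflexive_and_transitive_on_suite(suite):
    tax, exprs = suite
    rng = random.Random(11)
    sample = rng.sample(exprs, 40)
    for e in sample:
        assert subsumes(e, e, tax)
    for a, b, c in zip(sample, sample[1:], sample[2:]):
        if subsumes(a, b, tax) and subsumes(b, c, tax):
            assert subsumes(a, c, tax)


def test_naive_pairings_are_formally_equivalent(red_short_profile, bundle, tax):
    crossed = PhenotypeProfile(
        "crossed",
        (
            make_simple_statement(bundle.term("red"), bundle.term("tail")),
            make_simple_statement(bundle.term("short"), bundle.term("eye")),
        ),
    )
    a = compose_profile(red_short_profile, CLASSIC_EQ, "naive")
    b = compose_profile(crossed, CLASSIC_EQ, "naive")
    assert equivalent(a, b, tax)


def test_haspheno_pairings_stay_distinct(red_short_profile, bundle, tax):
    crossed = PhenotypeProfile(
        "crossed",
        (
            make_simple_statement(bundle.term("red"), bundle.term("tail")),
            make_simple_statement(bundle.term("short"), bundle.term("eye")),
        ),
    )
    a = compose_profile(red_short_profile, CLASSIC_EQ, "haspheno")
    b = compose_profile(crossed, CLASSIC_EQ, "haspheno")
    assert not equivalent(a, b, tax)
    assert not subsumes(a, b, tax) and not subsumes(b, a, tax)


def test_haspheno_distinctness_certified_by_countermodel(red_short_profile, bundle, tax):
    """Independent certificate: a hand-built intended model of the red-eye /
    short-tail annotation satisfies its hasPheno composition but not the
    cross-paired one, so the two cannot be equivalent."""
    a = compose_profile(red_short_profile, CLASSIC_EQ, "haspheno")
    crossed = PhenotypeProfile(
        "crossed",
        (
            make_simple_statement(bundle.term("red"), bundle.term("tail")),
            make_simple_statement(bundle.term("short"), bundle.term("eye")),
        ),
    )
    b = compose_profile(crossed, CLASSIC_EQ, "haspheno")
    # organism(0) –hasPheno→ red(1) –inheresIn→ eye(2);
    #             –hasPheno→ short(3) –inheresIn→ tail(4)
    model = TreeModel(
        labels=(
            frozenset(),
            frozenset({"PATO:0000322", "PATO:0000014"}),
            frozenset({"MA:000261"}),
            frozenset({"PATO:0000574", "PATO:0000117"}),
            frozenset({"MA:0000008"}),
        ),
        children=(
            ((HAS_PHENO, 1), (HAS_PHENO, 3)),
            ((INHERES_IN, 2),),
            (),
            ((INHERES_IN, 4),),
            (),
        ),
    )
    assert evaluate(a, model) and not evaluate(b, model)


def test_equivalence_is_reflexive_on_suite(suite):
    tax, exprs = suite
    for e in exprs[:40]:
        assert equivalent(e, e, tax)


# ---------------------------------------------------------------------------
# Permutation diagnostics


def test_permutation_collapse_under_naive_composition(red_short_profile, tax):
    report = diagnose_permutations(red_short_profile, CLASSIC_EQ, "naive", tax)
    assert report.collapsed
    assert len(report.pairings) == 2


def test_no_permutation_collapse_under_haspheno(red_short_profile, tax):
    report = diagnose_permutations(red_short_profile, CLASSIC_EQ, "haspheno", tax)
    assert not report.collapsed
    assert len(report.equivalence_classes) == 2


def test_identical_statements_always_collapse(red_eye, tax):
    profile = PhenotypeProfile("twice", (red_eye, red_eye))
    for mode in ("naive", "haspheno"):
        assert diagnose_permutations(profile, CLASSIC_EQ, mode, tax).collapsed


@pytest.mark.parametrize("scheme", [ROLES_AS_PROPERTIES, ROLES_AS_CLASSES])
def test_contrast_holds_for_role_based_schemes_too(red_short_profile, tax, scheme):
    assert diagnose_permutations(red_short_profile, scheme, "naive", tax).collapsed
    assert not diagnose_permutations(red_short_profile, scheme, "haspheno", tax).collapsed


def test_universal_naive_haspheno_contrast(bundle, tax):
    """For any profile of pairwise-distinct simple statements with disjoint
    qualities, naive composition collapses and hasPheno composition does not."""
    qualities = ["red", "short", "morphology"]
    bearers = ["eye", "tail", "spleen"]
    profile = PhenotypeProfile(
        "k3",
        tuple(
            make_simple_statement(bundle.term(q), bundle.term(e))
            for q, e in zip(qualities, bearers)
        ),
    )
    naive = diagnose_permutations(profile, CLASSIC_EQ, "naive", tax)
    assert naive.collapsed and len(naive.pairings) == 6
    hp = diagnose_permutations(profile, CLASSIC_EQ, "haspheno", tax)
    assert not hp.collapsed and len(hp.equivalence_classes) == 6


def test_permutation_cap_and_shape_guards(red_eye, red_short_profile, tax, iron_spleen):
    with pytest.raises(SizeLimitError):
        diagnose_permutations(
            PhenotypeProfile("big", (red_eye,) * 7), CLASSIC_EQ, "naive", tax
        )
    with pytest.raises(ValueError):
        diagnose_permutations(
            PhenotypeProfile("rel", (red_eye, iron_spleen)), CLASSIC_EQ, "naive", tax
        )


# ---------------------------------------------------------------------------
# Oracle agreement


def test_oracle_agrees_on_satisfiability(suite):
    tax, exprs = suite
    for expr in exprs:
        assert (
            is_satisfiable(expr, tax).satisfiable
            == small_model_oracle("sat", [expr], tax)
        )


def test_oracle_agrees_on_subsumption_and_equivalence(suite):
    tax, exprs = suite
    rng = random.Random(13)
    for _ in range(60):
        a, b = rng.choice(exprs), rng.choice(exprs)
        assert subsumes(a, b, tax) == small_model_oracle("subsumes", [a, b], tax)
        assert equivalent(a, b, tax) == small_model_oracle("equivalent", [a, b], tax)


def test_oracle_agrees_on_derived_true_subsumptions(suite):
    # conjunct removal gives known-true subsumptions: exercises the oracle's
    # exhaustive (no-counterexample) sweep rather than early exits
    tax, exprs = suite
    checked = 0
    for expr in exprs:
        if not isinstance(expr, And) or checked >= 15:
            continue
        sup = expr.conjuncts[0]
        assert subsumes(sup, expr, tax)
        assert small_model_oracle("subsumes", [sup, expr], tax)
        checked += 1
    assert checked == 15


def test_normalization_preserves_oracle_satisfiability(suite):
    tax, exprs = suite
    for expr in exprs[:60]:
        assert small_model_oracle("sat", [expr], tax) == small_model_oracle(
            "sat", [normalize(expr).expr], tax
        )


def test_oracle_rejects_oversized_expressions(bundle, tax):
    deep = Some(INHERES_IN, Some(INHERES_IN, Some(INHERES_IN, Atom(bundle.term("eye")))))
    with pytest.raises(SizeLimitError):
        small_model_oracle("sat", [deep], tax, max_domain=3)
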