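"""Structural reasoner for the emitted class-expression fragment.

The compiler only ever emits EL-style expressions — atoms, intersections and
existential restrictions — over a background TBox of atomic subsumptions and
atomic disjointness.  For this fragment:

* satisfiability reduces to checking every conjunction node for a pair of
  effectively-disjoint atoms, with ``∃r.⊥ ⇒ ⊥`` propagated from fillers;
* subsumption is decided by a homomorphism search between description
  trees, which is sound and complete here (canonical-model argument);
* equivalence is mutual subsumption and, for satisfiable taxonomy-free
  inputs, coincides with canonical-form equality.

An independent brute-force oracle (:func:`small_model_oracle`) decides the
same relations by exhaustively enumerating small interpretations; it exists
so the structural procedures can be checked against ground truth in tests,
and is never used as the implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .compile import Scheme, compose_profile
from .errors import SizeLimitError, UnknownTermError
from .model import (
    And,
    Atom,
    ClassExpr,
    EQStatement,
    PhenotypeProfile,
    PropRef,
    Some,
    Taxonomy,
    iter_atoms,
    make_simple_statement,
)

__all__ = [
    "CanonicalForm", "normalize",
    "SatReport", "is_satisfiable",
    "subsumes", "equivalent",
    "PermutationReport", "diagnose_permutations",
    "small_model_oracle", "TreeModel", "evaluate", "enumerate_tree_models",
]


# ---------------------------------------------------------------------------
# Normalization


@dataclass(frozen=True)
class CanonicalForm:
    """A normalized expression plus its deterministic serialization."""

    expr: ClassExpr
    text: str


def _sort_key(expr: ClassExpr) -> Tuple:
    if isinstance(expr, Atom):
        return (0, expr.term.curie, "", "")
    if isinstance(expr, Some):
        return (1, expr.prop.name, expr.prop.kind, expr.filler.key())
    return (2, expr.key(), "", "")  # nested And cannot survive normalization


def _normalize(expr: ClassExpr) -> ClassExpr:
    if isinstance(expr, Atom):
        return expr
    if isinstance(expr, Some):
        return Some(expr.prop, _normalize(expr.filler))
    if isinstance(expr, And):
        flat: List[ClassExpr] = []
        for c in expr.conjuncts:
            n = _normalize(c)
            if isinstance(n, And):
                flat.extend(n.conjuncts)
            else:
                flat.append(n)
        seen: Dict[str, ClassExpr] = {}
        for c in flat:
            seen.setdefault(c.key(), c)
        parts = sorted(seen.values(), key=_sort_key)
        if len(parts) == 1:
            return parts[0]
        return And(tuple(parts))
    raise TypeError(f"not a ClassExpr: {expr!r}")


def normalize(expr: ClassExpr) -> CanonicalForm:
    """Flatten, deduplicate and sort intersections (idempotent).

    Exploits only the commutativity/associativity/idempotence of
    intersection, so normalization is semantics-preserving; two expressions
    that differ only in conjunct order/nesting share one canonical text.
    """
    n = _normalize(expr)
    return CanonicalForm(n, n.key())


# ---------------------------------------------------------------------------
# Satisfiability


@dataclass(frozen=True)
class SatReport:
    """Satisfiability verdict; ``clash`` names the two offending atoms and
    the existential path (property names) from the root to their node."""

    satisfiable: bool
    clash: Optional[Tuple[str, str, Tuple[str, ...]]] = None


def _check_declared(expr: ClassExpr, tax: Taxonomy) -> None:
    for atom in iter_atoms(expr):
        if atom.term.curie not in tax:
            raise UnknownTermError(f"atom {atom.term.curie} not declared in taxonomy")


def _find_clash(expr: ClassExpr, tax: Taxonomy, path: Tuple[str, ...]):
    if isinstance(expr, Atom):
        return None
    if isinstance(expr, Some):
        return _find_clash(expr.filler, tax, path + (expr.prop.name,))
    atoms = [c.term.curie for c in expr.conjuncts if isinstance(c, Atom)]
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            if tax.effectively_disjoint(a, b):
                return (a, b, path)
    for c in expr.conjuncts:
        if isinstance(c, Some):
            clash = _find_clash(c.filler, tax, path + (c.prop.name,))
            if clash is not None:
                return clash
    return None


def is_satisfiable(expr: ClassExpr, tax: Taxonomy) -> SatReport:
    """Decide satisfiability under the taxonomy's atomic disjointness.

    An expression is unsatisfiable iff some conjunction node carries two
    effectively-disjoint atoms, or some existential filler is itself
    unsatisfiable (``∃r.⊥ ⇒ ⊥``), applied recursively.
    """
    _check_declared(expr, tax)
    clash = _find_clash(normalize(expr).expr, tax, ())
    return SatReport(satisfiable=clash is None, clash=clash)


# ---------------------------------------------------------------------------
# Subsumption / equivalence


def _parts(expr: ClassExpr) -> Tuple[List[str], List[Some]]:
    """Split a normalized node into its atom curies and existential children."""
    conjuncts = expr.conjuncts if isinstance(expr, And) else (expr,)
    atoms = [c.term.curie for c in conjuncts if isinstance(c, Atom)]
    exts = [c for c in conjuncts if isinstance(c, Some)]
    return atoms, exts


def _hom(sup: ClassExpr, sub: ClassExpr, tax: Taxonomy, memo: Dict) -> bool:
    key = (sup.key(), sub.key())
    if key in memo:
        return memo[key]
    memo[key] = False  # cycle guard (trees: unused, but keeps search safe)
    sup_atoms, sup_exts = _parts(sup)
    sub_atoms, sub_exts = _parts(sub)
    ok = all(
        any(tax.is_subclass_of(b, a) for b in sub_atoms) for a in sup_atoms
    ) and all(
        any(
            e.prop == s.prop and _hom(s.filler, e.filler, tax, memo)
            for e in sub_exts
        )
        for s in sup_exts
    )
    memo[key] = ok
    return ok


def subsumes(sup: ClassExpr, sub: ClassExpr, tax: Taxonomy) -> bool:
    """True iff every instance of ``sub`` is an instance of ``sup``.

    Decided structurally: an unsatisfiable ``sub`` is subsumed by everything
    (⊥ convention); otherwise a homomorphism from ``sup``'s description tree
    into ``sub``'s is sought, with told atomic subsumption at the leaves.
    """
    _check_declared(sup, tax)
    _check_declared(sub, tax)
    if not is_satisfiable(sub, tax).satisfiable:
        return True
    return _hom(normalize(sup).expr, normalize(sub).expr, tax, {})


def equivalent(a: ClassExpr, b: ClassExpr, tax: Taxonomy) -> bool:
    """Mutual subsumption."""
    return subsumes(a, b, tax) and subsumes(b, a, tax)


# ---------------------------------------------------------------------------
# Permutation diagnostics


@dataclass(frozen=True)
class PermutationReport:
    """Outcome of pairing qualities with permuted bearers.

    ``pairings`` lists the distinct quality→bearer bijections (as tuples of
    (quality curie, bearer curie) pairs); ``equivalence_classes`` partitions
    them by mutual logical equivalence of the composed expressions.
    ``collapsed`` is true iff the encoding cannot distinguish any pairing
    from the intended one (a single equivalence class).
    """

    scheme: Scheme
    mode: str
    pairings: Tuple[Tuple[Tuple[str, str], ...], ...]
    equivalence_classes: Tuple[Tuple[Tuple[Tuple[str, str], ...], ...], ...]

    @property
    def collapsed(self) -> bool:
        return len(self.equivalence_classes) == 1


def diagnose_permutations(
    profile: PhenotypeProfile,
    scheme: Scheme,
    mode: str,
    tax: Taxonomy,
    *,
    max_statements: int = 6,
    slot_map: str = "standard",
) -> PermutationReport:
    """Test whether an encoding collapses under quality↔bearer permutation.

    For a profile of k simple statements, every bijection of the k qualities
    onto the multiset of bearer entities is compiled and composed under
    (scheme, mode); pairings are then partitioned by :func:`equivalent`.  A
    collapsed report means queries against the encoding cannot tell the
    intended pairing from any permuted one.
    """
    stmts = profile.statements
    if len(stmts) < 2:
        raise ValueError("permutation diagnosis needs at least two statements")
    if len(stmts) > max_statements:
        raise SizeLimitError(
            f"profile has {len(stmts)} statements; cap is {max_statements} (k! pairings)"
        )
    if not all(s.is_simple for s in stmts):
        raise ValueError("permutation diagnosis is defined for simple statements only")
    qualities = [(s.quality, s.qualifier) for s in stmts]
    bearers = [s.roles[0].filler for s in stmts]
    pairings = []
    exprs = {}
    for perm in itertools.permutations(range(len(bearers))):
        pairing = tuple(
            (qualities[i][0].curie, bearers[j].curie) for i, j in enumerate(perm)
        )
        if pairing in exprs:
            continue
        permuted = PhenotypeProfile(
            profile_id=profile.profile_id,
            statements=tuple(
                make_simple_statement(qualities[i][0], bearers[j], qualities[i][1])
                for i, j in enumerate(perm)
            ),
        )
        exprs[pairing] = compose_profile(permuted, scheme, mode, slot_map=slot_map)
        pairings.append(pairing)
    classes: List[List] = []
    for pairing in pairings:
        for cls in classes:
            if equivalent(exprs[cls[0]], exprs[pairing], tax):
                cls.append(pairing)
                break
        else:
            classes.append([pairing])
    return PermutationReport(
        scheme=scheme,
        mode=mode,
        pairings=tuple(pairings),
        equivalence_classes=tuple(tuple(c) for c in classes),
    )


# ---------------------------------------------------------------------------
# Small-model oracle


@dataclass(frozen=True)
class TreeModel:
    """A rooted tree interpretation.

    ``labels[i]`` is the (ancestor-closed, disjointness-consistent) set of
    atom curies holding at node ``i``; ``children[i]`` lists
    ``(prop, child index)`` pairs.  Node 0 is the root.
    """

    labels: Tuple[frozenset, ...]
    children: Tuple[Tuple[Tuple[PropRef, int], ...], ...]


def evaluate(expr: ClassExpr, model: TreeModel, node: int = 0) -> bool:
    """Model-check: does ``node`` of ``model`` satisfy ``expr``?"""
    if isinstance(expr, Atom):
        return expr.term.curie in model.labels[node]
    if isinstance(expr, And):
        return all(evaluate(c, model, node) for c in expr.conjuncts)
    if isinstance(expr, Some):
        return any(
            prop == expr.prop and evaluate(expr.filler, model, child)
            for prop, child in model.children[node]
        )
    raise TypeError(f"not a ClassExpr: {expr!r}")


def _count_some(expr: ClassExpr) -> int:
    if isinstance(expr, Atom):
        return 0
    if isinstance(expr, Some):
        return 1 + _count_some(expr.filler)
    return sum(_count_some(c) for c in expr.conjuncts)


def _signature(exprs: Sequence[ClassExpr], tax: Taxonomy):
    atoms: set = set()
    props: set = set()
    for e in exprs:
        for a in iter_atoms(e):
            atoms.add(a.term.curie)
            atoms.update(tax.ancestors(a.term.curie))
        stack = [e]
        while stack:
            x = stack.pop()
            if isinstance(x, Some):
                props.add(x.prop)
                stack.append(x.filler)
            elif isinstance(x, And):
                stack.extend(x.conjuncts)
    return sorted(atoms), sorted(props, key=lambda p: (p.kind, p.name))


def _consistent_label_sets(atoms: Sequence[str], tax: Taxonomy) -> List[frozenset]:
    out = []
    for r in range(len(atoms) + 1):
        for combo in itertools.combinations(atoms, r):
            s = frozenset(combo)
            if any((tax.ancestors(a) & set(atoms)) - s for a in s):
                continue  # not ancestor-closed within the signature
            if any(
                tax.effectively_disjoint(a, b)
                for a, b in itertools.combinations(sorted(s), 2)
            ):
                continue
            out.append(s)
    return out


def enumerate_tree_models(
    atoms: Sequence[str],
    props: Sequence[PropRef],
    tax: Taxonomy,
    max_nodes: int,
) -> Iterable[TreeModel]:
    """Yield every rooted tree interpretation with at most ``max_nodes``
    nodes over the given signature (all shapes × edge labelings × node
    labelings).  The emitted fragment has the tree-model property, so this
    enumeration is exhaustive for (un)satisfiability and subsumption
    counterexamples whose witnesses fit in ``max_nodes``."""
    label_sets = _consistent_label_sets(atoms, tax)
    edge_labels = [
        frozenset(c)
        for r in range(1, len(props) + 1)
        for c in itertools.combinations(props, r)
    ] or [frozenset()]
    for n in range(1, max_nodes + 1):
        parent_choices = [range(i) for i in range(1, n)]
        for parents in itertools.product(*parent_choices):
            edge_space = [edge_labels] * (n - 1) if n > 1 else [[]]
            for edges in itertools.product(*([edge_labels] * (n - 1))):
                child_lists: List[List[Tuple[PropRef, int]]] = [[] for _ in range(n)]
                usable = True
                for i, (p, lbls) in enumerate(zip(parents, edges), start=1):
                    if not lbls:
                        usable = False
                        break
                    for prop in lbls:
                        child_lists[p].append((prop, i))
                if not usable:
                    continue
                children = tuple(tuple(c) for c in child_lists)
                for labels in itertools.product(label_sets, repeat=n):
                    yield TreeModel(labels=labels, children=children)


def small_model_oracle(
    relation: str,
    exprs: Sequence[ClassExpr],
    tax: Taxonomy,
    max_domain: int = 3,
) -> bool:
    """Brute-force ground truth for ``sat`` / ``subsumes`` / ``equivalent``.

    Enumerates all rooted tree interpretations with at most ``max_domain``
    elements over the expressions' signature and decides the relation by
    model checking.  Exhaustiveness requires each expression's witness to
    fit, i.e. its existential-subterm count + 1 must not exceed
    ``max_domain``; larger inputs raise :class:`SizeLimitError`.  Intended
    as an independent comparator in tests, not as an implementation.
    """
    if relation not in ("sat", "subsumes", "equivalent"):
        raise ValueError(f"unknown relation {relation!r}")
    exprs = list(exprs)
    for e in exprs:
        _check_declared(e, tax)
        if _count_some(e) + 1 > max_domain:
            raise SizeLimitError(
                f"expression needs {_count_some(e) + 1} elements; max_domain={max_domain}"
            )
    atoms, props = _signature(exprs, tax)
    models = enumerate_tree_models(atoms, props, tax, max_domain)
    if relation == "sat":
        (expr,) = exprs
        return any(evaluate(expr, m) for m in models)
    sup, sub = exprs
    if relation == "subsumes":
        return not any(evaluate(sub, m) and not evaluate(sup, m) for m in models)
    for m in models:
        va, vb = evaluate(sup, m), evaluate(sub, m)
        if va != vb:
            return False
    return True
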