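# Methods

This note records the models behind `eqowl`, the choices made where the
design was genuinely open, and what the tests do and do not establish.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The EQ data model

An `EQStatement` is a quality term plus an ordered list of named role
assignments, optionally a relation (relator) term, a qualifier, and a
measurement. One data model covers both statement shapes:

- A **simple** statement has exactly one role with the reserved label
  `bearer`. The label is an internal device — the inherence slot has no
  named role category in the EQ tradition — and it is never reified into
  generated vocabulary: simple qualities compile to `Q ⊓ ∃inheresIn.E`
  under every quality-headed scheme.
- A **relational** statement carries two or more named role assignments
  (one or more when its `RelationSpec` permits). Role order is significant
  only as input to the classic-EQ slot mapping and for deterministic
  serialization; all role-based schemes treat the roles as a multiset.

A `RelationSpec` is the role base of a relation: the admissible role
categories, arity bounds (`max_arity=None` for anadic relations), and
whether a category is multiply instantiable (`allow_repeats`) — the carrier
for symmetric relations such as *distance*, where both arguments play the
same `relatum` role. Repetition under roles-as-properties reuses one
generated property across several restrictions; under roles-as-classes it
produces several `∃hasRole` conjuncts over one role class.

Measurements are `(Decimal, unit-string)` with no unit algebra; they
survive in the annotation database (and statement objects) but are *not*
compiled into class expressions — measurement semantics for OWL is an open
design space, and committing to a datatype-property encoding here would be
arbitrary.

The qualifier compiles as one extra atomic conjunct next to the head
(quality or relation) atom. This is the minimal logical reading of the
qualifier column; qualifiers deserve a richer treatment (why is *abnormal*
a qualifier while *increased* is baked into quality names?), which is out
of scope here — the data model carries them, the logic does not interpret
them further.

## Background TBox

A `Taxonomy` is an atomic subclass DAG plus unordered atomic disjointness
pairs, inherited downward: `a` and `b` are *effectively disjoint* iff some
ancestor-or-self pair is declared disjoint. There is no general concept
disjointness — atomic disjointness between family roots (color / size /
morphology) is exactly what the worked examples need and keeps every
reasoning procedure simple and complete. Construction rejects cycles,
undeclared CURIEs, self-disjointness, and disjointness between
hierarchically related terms.

## Compilation schemes

For a statement with quality `Q`, relation `R`, role labels `rᵢ` and
fillers `Eᵢ` (qualifier omitted):

| scheme | output |
|---|---|
| `classic_eq`, simple | `Q ⊓ ∃inheresIn.E` |
| `classic_eq`, binary relational | `Q ⊓ ∃inheresIn.E₁ ⊓ ∃towards.E₂` |
| `entity_focused` (simple only) | `E ⊓ ∃hasQuality.Q` |
| `roles_as_properties` | `R ⊓ ∃o_r₁.E₁ ⊓ … ⊓ ∃o_rₙ.Eₙ` |
| `roles_as_classes` | `R ⊓ ∃hasRole.(Role₁ ⊓ ∃playedBy.E₁) ⊓ …` |
| `relator_based_quality` | `Q ⊓ ∃inheresIn.(relation under the sub-scheme)` |

Notes and choices:

- **Slot map.** Classic-EQ relational compilation assigns role index 0 to
  `inheresIn` and index 1 to `towards` by default; `slot_map="reversed"`
  swaps them (the convention preferred by analyses that put inherence in
  the concentrated entity). Because this assignment is precisely the
  inter-modeler ambiguity the role-based schemes exist to remove, every
  relational classic compilation logs a warning. Arity > 2 raises — the
  expressiveness limit is surfaced, not worked around.
- **Generated names.** Role properties are camel-cased role labels; role
  classes are capitalized labels under the `GEN:` namespace. A generated
  name colliding with a fixed property or a declared term raises rather
  than silently reusing vocabulary.
- **Relator head.** When a statement carries no relation term, the
  role-based schemes head the expression with the quality itself;
  `relator_based_quality` requires the explicit relator term and raises
  otherwise, since its whole point is distinguishing the relation (CI) from
  the quality that inheres in its instances (CO).
- **Composition.** `naive` intersects the compiled statements (flattened);
  `haspheno` wraps each in `∃hasPheno.(…)` first. `hasPheno` is a plain
  object property with no further axiomatization — no property chains, no
  materialization; its chain-of-basic-relations semantics is checked
  extra-logically by the `justify` module.
- **Emission.** `emit_ontology` produces a self-contained document: all
  taxonomy terms, generated classes and named profile classes declared,
  taxonomy axioms carried over, one `EquivalentClasses` per profile.
  Output ordering is fully sorted, so serialization is byte-deterministic.
  Profile ids that are not CURIEs are namespaced under `PHENO:`.
- **Vocabulary accounting.** `vocab_inventory` counts generated classes and
  used object properties from a fresh compilation, never from a formula:
  roles-as-properties costs one property per argument (0 classes),
  roles-as-classes one class per distinct role category plus the two fixed
  properties, the relator form adds `inheresIn` on top of its sub-scheme.

## The structural reasoner

The compiler emits an EL-style fragment — atoms, intersections, existential
restrictions — over the atomic TBox above. The reasoner is deliberately
restricted to exactly this fragment (no negation, union, or universal
restriction), which keeps every procedure sound and complete:

- **Normalization** flattens nested intersections, deduplicates conjuncts
  and sorts them by (node kind, atom CURIE / property name + filler form).
  It exploits only commutativity, associativity and idempotence of
  intersection, so it is semantics-preserving and idempotent; canonical
  text equality is syntactic equivalence modulo those laws.
- **Satisfiability**: a conjunction node containing two effectively
  disjoint atoms is a clash; `∃r.⊥` propagates `⊥` upward. The report
  carries the clashing pair and the existential path to it.
- **Subsumption** is a homomorphism search from the subsumer's description
  tree into the subsumee's, with told atomic subsumption at the leaves and
  the standard `⊥ ⊑ everything` convention checked first. Exhaustive with
  memoization — expressions here are tiny, heuristics would be noise.
- **Permutation diagnostics** enumerate all bijections of k qualities onto
  the multiset of bearers (k ≤ 6; k! growth), compile each pairing, and
  partition by mutual equivalence. `collapsed` means one equivalence class:
  the encoding cannot distinguish the intended pairing.

### The small-model oracle

Tests compare the structural procedures against an independent brute-force
decision procedure. The fragment has the tree-model property, and the
canonical model of an expression has one element per existential subterm
plus a root; the oracle therefore enumerates *all* rooted tree
interpretations with at most `max_domain` (default 3) nodes — every shape,
every nonempty edge labeling over the expressions' properties, every
ancestor-closed disjointness-consistent node labeling over their atoms —
and decides sat/subsumption/equivalence by model checking. An expression
whose witness cannot fit (existential count + 1 > `max_domain`) raises a
size error rather than answering incompletely. The random suites are sized
so the oracle is exhaustive: depth ≤ 1, at most two existentials, at most
four atoms per expression. For one claim whose countermodel needs five
elements (the distinctness of a two-statement hasPheno composition from its
cross-paired variant), the test instead model-checks a hand-built
countermodel with the oracle's evaluator — still independent of the
subsumption code path.

## hasPheno justification

Instance graphs are directed multigraphs of typed individuals. A
`hasPheno(bearer, pheno)` link is justified iff a chain of allowed basic
relations connects pheno to bearer. Choices: edges are traversable in both
directions (the chain must *connect* the entities; part-of vs has-part
dialects should not matter — the result records the traversal direction per
hop); the default allowed set is {inheres-in, part-of, has-function,
participates-in, has-role, role-of, plays, played-by} and is configurable,
as any such list is open-ended; `hasPheno` itself is banned from the
allowed set; breadth-first search returns a shortest chain, and a path
longer than `max_depth` (default 10 — generous, the worked examples need at
most 4) reports `depth-exceeded` as distinct from `no-path`. A chain may
pass through another pheno individual; nothing in the justification idea
forbids it.

## Annotation database

Three TSV tables: phenotype `(r_id, p_id, quality, role, entity,
qualifier)`, entity `(e_id, opaque attributes)`, annotation `(e_id, p_id,
measured_value, measuring_unit)`. Role information is row-wise — one row
per (p_id, role) — so arity is unbounded without schema changes. Cells hold
bare CURIEs (fused label+identifier renderings are ambiguous to parse;
labels belong to the taxonomy file). Empty role cells and the `N/A`
rendering both mean "simple quality row". Validation reports all
violations with row numbers: duplicate `r_id`, duplicate `(e_id, p_id)`,
dangling `p_id`, mixed qualifiers within a group, value/unit present
without the other, groups mixing simple and relational rows.

Conversion choices:

- A relational group's role list follows `r_id` order; its relator term is
  supplied by an optional quality→relation lookup, since the table schema
  has no relation column.
- Measurements attach to the statements of the annotated `(e_id, p_id)`
  pair, so the same phenotype can be measured for one entity and
  unmeasured for another while sharing a `p_id` on write.
- **Known limitation:** profiles do not retain the grouping of several
  simple rows under one `p_id`; on write each simple statement gets its own
  `p_id`. Equality "up to renumbering" is therefore checked on group
  content, and databases using multi-simple-row groups will round-trip to a
  finer grouping.

## Synthetic generators

`GeneratorConfig` defaults describe a small structured corpus: 12 entity
stubs, 9 qualities in 3 mutually disjoint families (mirroring the
color/size/morphology split), 30 distinct statements, 40 % relational with
arity weights {2: 3, 3: 1} — binary relations dominate real annotation
data, ternary ones exercise the arity machinery. Quality forests are depth
≤ 3 to keep the oracle tractable. Generated relational statements always
conform to their generated role bases and carry their relation terms.
Infeasible configurations (more distinct simple statements requested than
exist, zero-weight arity tables, more families than qualities) raise
config errors rather than looping.

What the generators emulate — and what they do not: they produce
structurally realistic statement mixes over stub vocabularies, not
excerpts of real PATO/MA/CHEBI releases. Passing tests therefore establish
the representational properties of the encodings (emptiness, collapse,
invariance, round-trips) on faithful miniatures, not coverage of the real
ontologies' content or scale, and no reasoning-performance claims.

## Problem sizes

The test suite and acceptance script use: 500 random expressions for the
oracle-agreement sweep plus 150 random pairs for subsumption/equivalence
(exact agreement required, and observed), permutation profiles of k ≤ 3
statements (6 pairings), vocabulary sweeps over arities 2–5, and the
worked-example graphs of ≤ 7 nodes. These sizes give exhaustive oracle
coverage at the default domain bound; everything completes in seconds on
one CPU.
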