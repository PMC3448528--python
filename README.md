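# eqowl

Compile Entity–Quality (EQ) phenotype annotations into OWL class
expressions — under five alternative encoding schemes — and check, with a
built-in structural reasoner, what each encoding can and cannot distinguish.

## The problem

Model-organism databases and phenotype ontologies (HPO, MP, WPO) describe
phenotypes with the EQ formalism: an **entity** class from an anatomy or
process ontology combined with a **quality** class from PATO. A *red eye* is
the quality *red* (PATO:0000322) inhering in an *eye* (MA:000261):

```
Q ⊓ ∃inheresIn.E
```

Two well-known problems appear as soon as such classes are composed or made
relational:

1. **Naive composition is broken.** Intersecting *red eye* with *short
   tail* gives `red ⊓ ∃inheresIn.eye ⊓ short ⊓ ∃inheresIn.tail` — a
   necessarily empty class (*red* and *short* inherit the disjointness of
   *color* and *size*), and by commutativity of intersection it is formally
   equivalent to the crossed pairing (*red tail* and *short eye*), so
   queries return wrong answers. Encapsulating each statement under an
   annotation-level relation repairs both:
   `∃hasPheno.(red ⊓ ∃inheresIn.eye) ⊓ ∃hasPheno.(short ⊓ ∃inheresIn.tail)`.
2. **Relational qualities are under-specified.** *Concentration of iron in
   the spleen* is classically forced into
   `conc ⊓ ∃inheresIn.X ⊓ ∃towards.Y` — arity is capped at two and nothing
   fixes which entity goes in which slot (a biologist and a chemist may
   disagree). Role-based encodings name the arguments instead:

   | scheme | pattern |
   |---|---|
   | roles-as-properties | `conc ⊓ ∃concentrated.iron ⊓ ∃concentrator.spleen` |
   | roles-as-classes | `conc ⊓ ∃hasRole.(Concentrated ⊓ ∃playedBy.iron) ⊓ ∃hasRole.(Concentrator ⊓ ∃playedBy.spleen)` |
   | relator-based-quality | `conc ⊓ ∃inheresIn.(isConcentratedIn ⊓ ∃concentrated.iron ⊓ ∃concentrator.spleen)` |

   These support any arity, are invariant under argument order, and (in the
   relator form) make a relational quality unary again, so measurement
   machinery attaches to a single bearer.

`eqowl` makes all of these claims *executable*: every scheme is a compiler
from EQ statements to class expressions, every "this class is empty /
ambiguous / invariant" claim is a check the reasoner performs, and the
row-wise three-table annotation-database format shows the same content
translating into every scheme.

## What is in the box

- `eqowl.model` — terms, taxonomies (atomic subclass DAG + disjointness),
  EQ statements, role bases, and the class-expression AST.
- `eqowl.compile` — the five schemes (`classic_eq`, `entity_focused`,
  `roles_as_properties`, `roles_as_classes`, `relator_based_quality` with a
  role sub-scheme), naive vs. `hasPheno` composition, deterministic
  emission of OWL functional-style syntax, and vocabulary accounting.
- `eqowl.reason` — canonical normalization, satisfiability under atomic
  disjointness, structural subsumption/equivalence (sound and complete for
  the emitted EL-style fragment), permutation diagnostics, and an
  independent brute-force small-model oracle used by the test suite.
- `eqowl.justify` — checks that each `hasPheno` link is justified by a
  chain of basic relations (inheres-in, part-of, role/player links, …) on
  an instance graph.
- `eqowl.io` — the three-table TSV annotation database (phenotype / entity
  / annotation), taxonomy and instance-graph TSVs, and a round-tripping
  parser for the emitted OWL subset.
- `eqowl.fixtures` — programmatic worked examples (no downloads) and seeded
  synthetic generators for property testing.
- `eqowl` CLI — `compile`, `check`, `diagnose-permutations`, `justify`,
  `roundtrip`, `fixtures`.

## Worked example

```python
from eqowl import (make_simple_statement, PhenotypeProfile, compose_profile,
                   CLASSIC_EQ, is_satisfiable, diagnose_permutations)
from eqowl.fixtures import make_reference_bundle

bundle = make_reference_bundle()
red_eye = make_simple_statement(bundle.term("red"), bundle.term("eye"))
short_tail = make_simple_statement(bundle.term("short"), bundle.term("tail"))
profile = PhenotypeProfile("demo", (red_eye, short_tail))

for mode in ("naive", "haspheno"):
    expr = compose_profile(profile, CLASSIC_EQ, mode)
    report = is_satisfiable(expr, bundle.taxonomy)
    diag = diagnose_permutations(profile, CLASSIC_EQ, mode, bundle.taxonomy)
    print(f"{mode:9s} satisfiable={report.satisfiable!s:5s} "
          f"clash={report.clash} "
          f"pairings={len(diag.pairings)} classes={len(diag.equivalence_classes)} "
          f"collapsed={diag.collapsed}")
```

prints

```
naive     satisfiable=False clash=('PATO:0000322', 'PATO:0000574', ()) pairings=2 classes=1 collapsed=True
haspheno  satisfiable=True  clash=None pairings=2 classes=2 collapsed=False
```

Read: composed naively, the two-statement profile is unsatisfiable — the
clash names *red* (PATO:0000322) and *short* (PATO:0000574) at the top level
— and its two possible quality↔bearer pairings collapse into one
equivalence class (the encoding cannot say which entity is red and which is
short). Under `hasPheno` composition the class is satisfiable and the two
pairings stay logically distinct.

The same pipeline from the shell, using the bundled example database:

```bash
eqowl fixtures /tmp/bundle
eqowl compile --taxonomy /tmp/bundle/taxonomy.tsv \
    --phenotypes /tmp/bundle/phenotype.tsv --entities /tmp/bundle/entity.tsv \
    --annotations /tmp/bundle/annotation.tsv \
    --scheme roles_as_classes --compose haspheno --out /tmp/out.ofn
eqowl check /tmp/out.ofn          # per-class satisfiability, exit 1 on ⊥
eqowl justify /tmp/bundle/graph-organism-eye-red.tsv --audit
```

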