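# Methods

## The annotation-extension model

A GO annotation associates a gene product with a class from one of the
three GO sub-ontologies. An annotation extension refines the annotated
class with relational expressions `relation(DB:ID)`. The field grammar is

```
Field ::= Conj ('|' Conj)*
Conj  ::= Rel '(' Entity ')' (',' Rel '(' Entity ')')*
```

A comma means conjunction, a pipe disjunction; a disjunctive field is
equivalent to several independent annotations, one per conjunction
(`split_disjunction` materializes this). Nesting of expressions is not
allowed: the parser rejects a parenthesis inside a parenthesis with a
character offset, reserving parentheses for possible future nesting.
Entities are CURIEs with exactly one `prefix:localid` colon, and entity
prefixes are checked (exact, case-sensitive) against a database-abbreviation
registry. Whitespace after separators is tolerated on input and never
emitted, so serialization is canonical and `parse ∘ serialize` is the
identity.

Entities — including gene products — are modeled as OWL classes, not
individuals. A conjunction on term *t* translates to

*t* ⊓ ∃r₁.f₁ ⊓ … ⊓ ∃rₙ.fₙ

with one existential restriction per expression, in field order. This
stays within the EL++ profile (no negation, union or universal
quantification), which is what keeps classification polynomial. A
relation declared with a binary chain r = r₁ ∘ r₂ expands to
∃r₁.(∃r₂.f) and is re-folded to `r(f)` when translating back; the
inverse translation rejects anything outside this profile
(`NotExpressibleError`).

Relation labels map to object properties through the relation registry:
`part_of` → `BFO:0000050`, `occurs_in` → `BFO:0000066`, `regulates` →
`RO:0002211`, `happens_during` → `RO:0002092`, `has_input` →
`RO:0002233`. Relations with no established property identifier
(`has_direct_input`, `has_regulation_target`, `exists_during`, and the
chain relation `regulates_occurs_in` itself) render under a reserved
`GOREL:` namespace so translation is total and invertible. Rendered text
uses underscore-form identifiers (`GO_0005635`), joined by ` and ` with
every non-leading conjunct parenthesized; underscore form is accepted on
input everywhere and produced only by the renderer.

## Ontology model and OBO subset

The in-memory ontology holds named terms (with GO aspect), `is_a`
axioms, relationship axioms (child ⊑ ∃r.filler), genus–differentia
equivalence axioms (the OBO `intersection_of` pattern), pairwise
disjointness, and relation definitions with usage metadata
(allowed aspects of the primary term, allowed filler prefixes or
required-ancestor classes, range category, optional chain, subset tags).
The OBO reader honors exactly the tags this requires (`id`, `name`,
`namespace`, `is_a`, `relationship`, `intersection_of`, `is_obsolete`,
`subset`, `disjoint_from`; for typedefs `domain`, `range`,
`holds_over_chain`); unknown tags are ignored with a logged warning,
never an error, because real OBO files carry many tags irrelevant here.
Duplicate stanza ids and malformed `intersection_of` blocks (no genus,
no differentia, two genera) are hard errors naming the stanza. A writer
for the same subset exists for fixtures; `serialize ∘ parse` is stable
on it, and the reader is cross-checked against an independent OBO
library in the tests.

Obsolete terms are carried but excluded from reasoning and from MSC
candidacy. Cyclic `is_a` chains are tolerated and collapse into mutual
equivalence, as EL semantics allow.

## Reasoning

The reasoner implements the standard EL completion procedure:

1. **Normalization** rewrites all axioms into the normal forms
   A ⊑ B, A₁ ⊓ A₂ ⊑ B, A ⊑ ∃r.B, ∃r.A ⊑ B (plus role inclusions and
   binary role chains), introducing sequentially numbered fresh names
   for complex subexpressions. Fresh naming is deterministic in input
   order, so classification output is reproducible.
2. **Saturation** runs the completion rules (told subsumptions, binary
   conjunctions, existential introduction/elimination, role inclusion,
   binary role chains, bottom propagation along role links and through
   disjointness) to a fixed point with a worklist, yielding for every
   class its set of named subsumers and the set of unsatisfiable
   classes.

Range constraints are compiled rather than interpreted: every term gets
an upper-level category — biological-process and molecular-function
terms are occurrents, cellular-component and external terms (cells,
anatomy, chemicals) continuants, with explicit assignments able to
override — and a relation with a continuant range contributes
∃r.Occurrent ⊑ ⊥ against the disjoint Continuant/Occurrent markers
(BFO:0000002/BFO:0000003). The marker axioms are only materialized when
some relation actually constrains its range; they are inert otherwise.
This is what makes `occurs_in(<process>)` unsatisfiable.

Expression-level queries (subsumption, satisfiability, MSC) introduce a
fresh name defined equivalent to the query expression and read the
saturated index. The MSC of an expression is the set of minimal named,
non-fresh ontology terms subsuming it; incomparable minima are all
returned. Role chains are limited to length 2 — every chain in scope is
binary — and longer chains are rejected explicitly.

`brute_force_subsumption` is a deliberately independent oracle: a naive
closure over *unnormalized* expressions (transitivity, intersection
introduction/elimination, existential monotonicity, chain composition,
bottom propagation) iterated to a fixed point over the finite universe
of subexpressions occurring in the axioms and queries. It shares no
inference code with the completion engine and is capped at small inputs
(default 20 classes). The suite checks agreement between the two engines
on 100+ seeded random ontologies per run.

## Annotation operations

**Folding.** Disjunctions are split first, so corpus cardinality after
splitting is invariant. Each distinct (term, expression-as-set) pair
materializes one application-ontology term with the equivalence axiom
t^A ≡ t ⊓ e; folded-term ids are content-addressed (a stable hash of the
source term plus the canonicalized expression) under the reserved
`GOTEMP:` prefix, so repeated runs and merged corpora agree. After
classification, each folded term receives its inferred direct named
parents (at minimum its source term) as `is_a` axioms. An unsatisfiable
folded term is retained, flagged, and reported. Records with empty
extensions pass through; NOT-qualified records are excluded from folding
and deepening with a warning, because the interaction of negation with
extensions has no defined semantics; records using an undefined relation
pass through with an error entry.

**Unfolding.** A record on a term with an equivalence axiom t ≡ t′ ⊓ e —
where t′ is GO-prefixed, has the same aspect, and e lies inside the
extension profile — is rewritten to t′ with e appended conjunctively to
every existing conjunction (or forming a new one). Single-step by
default; the recursive mode iterates to a fixed point with cycle
protection. When several axioms are eligible the first in ontology order
is used and a warning recorded. Fold followed by unfold reproduces the
original corpus up to conjunct ordering and disjunction splitting, which
the suite verifies on 100 generated corpora.

**Validation** applies, in order: grammar re-check, relation existence,
entity-prefix membership, usage checks (primary-term aspect against the
relation's allowed aspects; filler against allowed prefixes or required
ancestors), satisfiability of each translated conjunction, and duplicate
expressions. Severities follow the distinction between hard incoherence
and guideline breaches: grammar, unknown relation, unregistered prefix
and unsatisfiability are errors; aspect/filler usage and duplicates are
warnings. All satisfiability queries for a corpus are answered from a
single classification. Findings are deterministic, ordered by
(record, rule), and reproducible from the record plus the supplied
ontologies alone.

**Deepening** computes the MSC of the translated expression. The term is
replaced only when the MSC is unique and strictly below the current
term. The extension is dropped only when the MSC is logically equivalent
to the whole expression (the named term then captures the full meaning);
otherwise it is retained unchanged, since dropping it would lose
information — e.g. *postsynaptic density* + `part_of(astrocyte)` deepens
to *glial cell postsynaptic density* but keeps `part_of(astrocyte)`,
which is strictly stronger than the term's `part_of(glial cell)`
differentia, whereas `part_of(glial cell)` itself is consumed. Ties
(incomparable minima) and disjunctive extensions leave the record
unchanged with a log note. Deepening is idempotent, which the suite
checks across fixture corpora.

## Synthetic fixtures

The fixture generator emulates the study inputs at desk scale: a
mini-GO (26 terms across the three aspects, including the
genus–differentia definition of *glial cell postsynaptic density*),
mini cell-type and anatomy ontologies, the relation typedef file, the
prefix registry, and a GAF 2.0 corpus. The corpus always contains the
canonical worked examples — the Nep1 annotation with three
`has_direct_input` targets, the mAKAP nuclear-envelope annotation with
two `part_of` expressions, a deepenable postsynaptic-density record, a
disjunctive record and unextended records — plus seed-dependent random
records (12 for `small`, 200 for `medium`) drawn from aspect-compatible
relation/filler pools so the clean corpus validates without findings. A
separate planted-defect corpus carries one instance each of an
unsatisfiable extension, an unregistered prefix, an undefined relation,
a duplicate expression and a short row. Output is byte-identical per
seed.

What the generator does **not** emulate: real ontology scale (full GO
has ~50,000 classes; reasoning here is tested to tens of classes plus
folded terms), the long tail of GAF dialect quirks (encoding issues,
qualifier vocabularies beyond NOT, isoform column semantics), curation
noise (wrong but satisfiable extensions), and the skewed per-species
extension frequencies of production corpora. Passing tests therefore
demonstrate correctness of the operations and their algebraic
properties, not performance or robustness at database scale. The
published per-species percent-extended figures are recomputed by
rebuilding corpora at the published (total, extended) sizes and running
the statistics operation on them; the published counts are inputs, not
outputs.

## Numerical and interface choices

- Percentages are rounded half-away-from-zero to one decimal (via
  `decimal`), matching how the per-species table is printed; banker's
  rounding would differ on exact halves.
- GAF 2.0 is written with 17 columns (extension in 1-based column 16),
  GAF 1.0 (15 columns) is accepted on read with an empty extension, and
  GPAD uses a 12-column layout with the extension at column 11; the
  extension string transfers verbatim between formats. Round trips are
  bit-exact per format on the columns the format carries; GAF-only
  columns have no GPAD slot and do not survive a GAF→GPAD conversion.
- Rows with fewer than 15 columns (GAF) or 11 (GPAD), and rows whose
  extension fails to parse, are collected as row-level errors and
  skipped; parsing continues.
- Conjunct order is preserved through translation so rendered strings
  are reproducible; semantic equality of expressions is order-insensitive
  where set semantics demand (`same_expression`).
- CLI exit codes: 0 clean, 1 findings (with `--strict`, warnings too),
  2 I/O or configuration failure.

## Known limitations

- The reasoner supports role inclusions and binary chains only — no
  inverse roles, nominals or concrete domains — and is not tuned for
  full-GO scale.
- Unfolding chooses deterministically among multiple eligible
  equivalence axioms rather than exploring alternatives.
- Whether folding should merge records that become identical after
  rewriting is left open; they are kept distinct.
- Deepening handles single-conjunction extensions; disjunctive fields
  must be split first.
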