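# goext — Gene Ontology annotation extensions

`goext` is a toolkit for working with **annotation extensions**: the
`Relation(Entity)` expressions that refine a GO annotation with contextual
or target detail (GAF 2.0 column 16, GPAD column 11). A basic annotation
pairs a gene product *G* with a GO class *C*; an extended annotation
refines *C* with one or more relational expressions, e.g.

```
GO:0005635 (nuclear envelope)   part_of(CL:0002495),part_of(UBERON:0002082)
```

meaning the gene product localizes to the nuclear envelope of fetal
cardiomyocytes of the cardiac ventricle. The library is for annotation
pipeline developers and curators who need to parse, validate, and reason
over such data.

## The model

An extension field is a disjunction (`|`) of conjunctions (`,`) of
`relation(DB:ID)` pairs. A conjunction on term *t* translates to the OWL
class expression

> *t* ⊓ ∃r₁.f₁ ⊓ … ⊓ ∃rₙ.fₙ

using only named classes, intersections and existential restrictions —
the EL++ profile, so classification stays polynomial. Relations defined
by a binary property chain (r = r₁ ∘ r₂, e.g.
`regulates_occurs_in` = `regulates` ∘ `occurs_in`) expand to nested
existentials. On top of this translation the package implements:

- **Validation by reasoning** — an extension like
  `occurs_in(<process>)` is flagged because the range of `occurs_in` is a
  continuant, making the expression unsatisfiable; plus registry,
  grammar and usage checks.
- **Folding** — each extended annotation (*t*, *e*) is rewritten as a
  basic annotation to a materialized term *t*ᴬ with the equivalence axiom
  *t*ᴬ ≡ *t* ⊓ *e*; the resulting application ontology is classified so
  legacy, extension-unaware tools see ordinary annotations without loss
  of meaning.
- **Unfolding** — the inverse: an annotation to a logically defined term
  *t* ≡ *t′* ⊓ *e* becomes an annotation to *t′* with *e* in the
  extension field.
- **Deepening** — an annotation is moved down to the Most Specific Class
  (MSC) entailed for its translated expression, e.g. *postsynaptic
  density* + `part_of(astrocyte)` deepens to *glial cell postsynaptic
  density* via its genus–differentia definition and astrocyte ⊑ glial
  cell.

A small EL completion reasoner (normalization to EL normal forms, then
saturation with the standard completion rules) backs all reasoning; an
independent brute-force oracle cross-checks it in the test suite.

## Worked example

```python
from goext import (
    generate_fixtures, parse_extension_field, conjunction_to_class_expression,
    render_owl, deepen, fold, validate, read_gaf,
)

bundle = generate_fixtures(seed=1)      # mini-GO/CL/Uberon + GAF corpus
onto = bundle.ontology

field = parse_extension_field("part_of(CL:0002495),part_of(UBERON:0002082)")
expr = conjunction_to_class_expression("GO:0005635", field.conjunctions[0])
print(render_owl(expr))

record = read_gaf(bundle.corpus_gaf).records[2]   # postsynaptic density + astrocyte
print(record.go_term, record.extension)
print(deepen(record, onto).go_term)

result = fold(read_gaf(bundle.corpus_gaf).records, onto)
print(len(result.mapping), "folded terms,", len(result.records), "records")

report = validate(read_gaf(bundle.invalid_gaf).records, onto, registry=bundle.registry)
for entry in report.errors:
    print(entry.rule, entry.message)
```

prints

```
GO_0005635 and (BFO_0000050 some CL_0002495) and (BFO_0000050 some UBERON_0002082)
GO:0014069 part_of(CL:0000127)
GO:0097483
14 folded terms, 24 records
UNSATISFIABLE expression GO:0004601 + occurs_in(GO:0006915) is unsatisfiable
PREFIX entity prefix 'NOPEDB' not in registry
UNKNOWN_RELATION unknown relation 'no_such_relation'
```

The first line is the OWL intersection the two-part extension translates
to. The nuclear-envelope record folds into a materialized term
classified under GO:0005635; the postsynaptic-density record deepens to
the pre-composed glial-cell term; and the planted-defect corpus triggers
one reasoning error (a process used where a continuant is required) plus
two registry/grammar errors.

The same workflows are available from the shell:

```sh
goext fixtures --seed 1 --out fx
goext validate fx/corpus.gaf --ontology fx/go-mini.obo --ontology fx/cl-mini.obo \
    --ontology fx/uberon-mini.obo --relations fx/gorel-mini.obo --registry fx/registry.tsv
goext fold fx/corpus.gaf --ontology fx/go-mini.obo --ontology fx/cl-mini.obo \
    --ontology fx/uberon-mini.obo --out folded.gaf --out-ontology app.obo
goext stats fx/corpus.gaf
```

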