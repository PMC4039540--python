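"""Synthetic fixture generation: mini ontologies and annotation corpora.

Everything a full workflow needs is generated in memory, deterministically
per seed: a miniature GO covering the three aspects, miniature cell-type
(CL) and anatomy (Uberon) ontologies, a relations typedef file, a
database-abbreviation registry and a GAF 2.0 corpus.  The corpus always
contains the canonical worked examples — the S. pombe Nep1 deneddylation
annotation with three has_direct_input targets, the rat mAKAP nuclear
envelope annotation with cell- and tissue-level part_of context, and a
postsynaptic-density annotation with an astrocyte part_of extension that
reasoning can deepen — alongside seed-dependent unextended, conjunctive
and disjunctive records.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .extension_syntax import AnnotationRecord, ParseResult, read_gaf, write_gaf
from .ontology_model import (
    EquivalenceAxiom,
    IdRegistry,
    Ontology,
    OntologyTerm,
    RelationDef,
    builtin_relations,
    serialize_obo,
)

NEP1_EXTENSION = (
    "has_direct_input(PomBase:SPAC17G6.12),"
    "has_direct_input(PomBase:SPAC24H6.03),"
    "has_direct_input(PomBase:SPAC3A11.08)"
)
MAKAP_EXTENSION = "part_of(CL:0002495),part_of(UBERON:0002082)"

GLIAL_CELL = "CL:0000243"
ASTROCYTE = "CL:0000127"
POSTSYNAPTIC_DENSITY = "GO:0014069"
GLIAL_PSD = "GO:0097483"
APOPTOSIS = "GO:0006915"


@dataclass
class FixtureBundle:
    """All generated artifacts, as parsed objects and as flat-file text."""

    go: Ontology
    cl: Ontology
    uberon: Ontology
    relations: dict[str, RelationDef]
    registry: IdRegistry
    go_obo: str
    cl_obo: str
    uberon_obo: str
    relations_obo: str
    registry_tsv: str
    corpus_gaf: str
    invalid_gaf: str
    seed: int = 0
    size: str = "small"

    @property
    def ontology(self) -> Ontology:
        """GO + CL + Uberon + relations merged for reasoning."""
        merged = self.go.merge(self.cl).merge(self.uberon)
        for rel in self.relations.values():
            if rel.label not in merged.relations:
                merged.relations[rel.label] = rel
        return merged

    def corpus_records(self) -> ParseResult:
        return read_gaf(self.corpus_gaf)


def _mini_go() -> Ontology:
    onto = Ontology()

    def term(tid: str, label: str, aspect: str, *parents: str) -> None:
        onto.add_term(OntologyTerm(id=tid, label=label, aspect=aspect))
        for p in parents:
            onto.subclass_axioms.append((tid, p))

    # molecular function
    term("GO:0003674", "molecular_function", "molecular_function")
    term("GO:0003824", "catalytic activity", "molecular_function", "GO:0003674")
    term("GO:0008233", "peptidase activity", "molecular_function", "GO:0003824")
    term("GO:0019784", "NEDD8-specific protease activity", "molecular_function", "GO:0008233")
    term("GO:0016301", "kinase activity", "molecular_function", "GO:0003824")
    term("GO:0004672", "protein kinase activity", "molecular_function", "GO:0016301")
    term("GO:0004601", "peroxidase activity", "molecular_function", "GO:0003824")
    term("GO:0008020", "G-protein coupled photoreceptor activity", "molecular_function", "GO:0003674")
    # biological process
    term("GO:0008150", "biological_process", "biological_process")
    term("GO:0008219", "cell death", "biological_process", "GO:0008150")
    term("GO:0006915", "apoptotic process", "biological_process", "GO:0008219")
    term("GO:0050896", "response to stimulus", "biological_process", "GO:0008150")
    term("GO:0071470", "cellular response to osmotic stress", "biological_process", "GO:0050896")
    term("GO:0007165", "signal transduction", "biological_process", "GO:0050896")
    term("GO:0051403", "stress-activated MAPK cascade", "biological_process", "GO:0007165")
    term("GO:0006508", "proteolysis", "biological_process", "GO:0008150")
    term("GO:0000338", "protein deneddylation", "biological_process", "GO:0006508")
    term("GO:0065007", "biological regulation", "biological_process", "GO:0008150")
    term("GO:0006357", "regulation of transcription by RNA polymerase II",
         "biological_process", "GO:0065007")
    # cellular component
    term("GO:0005575", "cellular_component", "cellular_component")
    term("GO:0043226", "organelle", "cellular_component", "GO:0005575")
    term("GO:0005634", "nucleus", "cellular_component", "GO:0043226")
    term("GO:0005635", "nuclear envelope", "cellular_component", "GO:0005575")
    onto.relationship_axioms.append(("GO:0005635", "part_of", "GO:0005634"))
    term("GO:0045202", "synapse", "cellular_component", "GO:0005575")
    term("GO:0014069", "postsynaptic density", "cellular_component", "GO:0045202")
    term("GO:0097483", "glial cell postsynaptic density", "cellular_component", "GO:0014069")
    onto.equivalence_axioms.append(
        EquivalenceAxiom(GLIAL_PSD, POSTSYNAPTIC_DENSITY, (("part_of", GLIAL_CELL),))
    )
    return onto


def _mini_cl() -> Ontology:
    onto = Ontology()

    def term(tid: str, label: str, *parents: str) -> None:
        onto.add_term(OntologyTerm(id=tid, label=label, aspect="external"))
        for p in parents:
            onto.subclass_axioms.append((tid, p))

    term("CL:0000000", "cell")
    term("CL:0000540", "neuron", "CL:0000000")
    term("CL:0000740", "retinal ganglion cell", "CL:0000540")
    term(GLIAL_CELL, "glial cell", "CL:0000000")
    term(ASTROCYTE, "astrocyte", GLIAL_CELL)
    term("CL:0000746", "cardiac muscle cell", "CL:0000000")
    term("CL:0002495", "fetal cardiomyocyte", "CL:0000746")
    term("CL:0000312", "keratinocyte", "CL:0000000")
    term("CL:0000066", "epithelial cell", "CL:0000000")
    return onto


def _mini_uberon() -> Ontology:
    onto = Ontology()

    def term(tid: str, label: str, *parents: str) -> None:
        onto.add_term(OntologyTerm(id=tid, label=label, aspect="external"))
        for p in parents:
            onto.subclass_axioms.append((tid, p))

    term("UBERON:0000061", "anatomical structure")
    term("UBERON:0000948", "heart", "UBERON:0000061")
    term("UBERON:0002082", "cardiac ventricle", "UBERON:0000061")
    onto.relationship_axioms.append(("UBERON:0002082", "part_of", "UBERON:0000948"))
    term("UBERON:0000955", "brain", "UBERON:0000061")
    term("UBERON:0002421", "hippocampal formation", "UBERON:0000061")
    onto.relationship_axioms.append(("UBERON:0002421", "part_of", "UBERON:0000955"))
    return onto


REGISTRY_PREFIXES = {
    "GO": "Gene Ontology Consortium",
    "CL": "Cell Type Ontology",
    "UBERON": "Uber-anatomy ontology",
    "PO": "Plant Ontology Consortium",
    "CHEBI": "Chemical Entities of Biological Interest",
    "UniProtKB": "Universal Protein Knowledgebase",
    "PomBase": "Fission yeast database",
    "SGD": "Saccharomyces Genome Database",
    "MGI": "Mouse Genome Informatics",
    "RGD": "Rat Genome Database",
    "WB": "WormBase",
    "WBbt": "C. elegans gross anatomy",
    "FB": "FlyBase",
    "TAIR": "The Arabidopsis Information Resource",
    "dictyBase": "Dictyostelium genome database",
}


def _gaf_row(
    db: str, oid: str, symbol: str, go_term: str, aspect: str, taxon: str,
    evidence: str = "IDA", extension: str = "", qualifier: str = "",
    reference: str = "PMID:1", obj_type: str = "protein",
) -> str:
    return "\t".join(
        [db, oid, symbol, qualifier, go_term, reference, evidence, "", aspect,
         "", "", obj_type, taxon, "20130501", db, extension, ""]
    )


_WORKED_ROWS = [
    # Nep1 deneddylates the cullins Cul1, Cul3 and Pcu4: one annotation,
    # three has_direct_input expressions
    _gaf_row("PomBase", "SPAC23H4.01", "nep1", "GO:0019784", "F", "taxon:4896",
             evidence="IMP", extension=NEP1_EXTENSION),
    # mAKAP on the nuclear envelope of fetal cardiomyocytes of the cardiac ventricle
    _gaf_row("RGD", "620875", "Akap6", "GO:0005635", "C", "taxon:10116",
             extension=MAKAP_EXTENSION),
    # postsynaptic density located in an astrocyte: deepens to GO:0097483
    _gaf_row("MGI", "MGI:1277959", "Dlg4", "GO:0014069", "C", "taxon:10090",
             extension="part_of(CL:0000127)"),
    # opsin photoreceptor activity in retinal ganglion cells
    _gaf_row("MGI", "MGI:1353425", "Opn4", "GO:0008020", "F", "taxon:10090",
             extension="occurs_in(CL:0000740)"),
    # wis4 MAPK cascade during osmotic stress response
    _gaf_row("PomBase", "SPBC1778.10c", "wis4", "GO:0051403", "P", "taxon:4896",
             evidence="IMP", extension="happens_during(GO:0071470)"),
    # nucleus of a keratinocyte
    _gaf_row("UniProtKB", "P0TEST1", "KRTX", "GO:0005634", "C", "taxon:9606",
             extension="part_of(CL:0000312)"),
    # disjunctive context: two independent cell types
    _gaf_row("MGI", "MGI:2159711", "Gpr12", "GO:0008020", "F", "taxon:10090",
             extension="occurs_in(CL:0000740)|occurs_in(CL:0000540)"),
    # kinase activity in hippocampal neurons (conjunction of cell + anatomy)
    _gaf_row("RGD", "2321", "Camk2a", "GO:0004672", "F", "taxon:10116",
             extension="occurs_in(CL:0000540),occurs_in(UBERON:0002421)"),
    # unextended annotations
    _gaf_row("PomBase", "SPAC23H4.01", "nep1", "GO:0000338", "P", "taxon:4896",
             evidence="IMP"),
    _gaf_row("RGD", "620875", "Akap6", "GO:0005634", "C", "taxon:10116"),
    _gaf_row("SGD", "S000004660", "YLR113W", "GO:0004672", "F", "taxon:559292"),
]

_INVALID_ROWS = [
    # occurs_in with a process filler: unsatisfiable (range of occurs_in is a continuant)
    _gaf_row("PomBase", "SPAC1002.01", "bad1", "GO:0004601", "F", "taxon:4896",
             extension=f"occurs_in({APOPTOSIS})"),
    # entity prefix not in the database-abbreviation registry
    _gaf_row("UniProtKB", "P0TEST2", "bad2", "GO:0004672", "F", "taxon:9606",
             extension="has_direct_input(NOPEDB:12345)"),
    # undefined relation label
    _gaf_row("UniProtKB", "P0TEST3", "bad3", "GO:0004672", "F", "taxon:9606",
             extension="no_such_relation(CL:0000540)"),
    # duplicated expression within one conjunction (warning, not error)
    _gaf_row("UniProtKB", "P0TEST4", "bad4", "GO:0005634", "C", "taxon:9606",
             extension="part_of(CL:0000312),part_of(CL:0000312)"),
    # malformed row: too few columns
    "UniProtKB\tP0TEST5\tbad5\t\tGO:0005634",
]

_RANDOM_POOLS = {
    # aspect -> (GO terms, candidate extensions)
    "F": (
        ["GO:0004672", "GO:0004601", "GO:0016301", "GO:0008020"],
        ["occurs_in(CL:0000540)", "occurs_in(CL:0000312)", "occurs_in(CL:0000066)",
         "has_direct_input(UniProtKB:P12345)", "has_input(PomBase:SPAC17G6.12)", ""],
    ),
    "P": (
        ["GO:0006508", "GO:0007165", "GO:0071470", "GO:0006357", "GO:0000338"],
        ["occurs_in(CL:0000740)", "happens_during(GO:0071470)",
         "has_regulation_target(UniProtKB:P08151)",
         "regulates_occurs_in(CL:0000540)", "", ""],
    ),
    "C": (
        ["GO:0005634", "GO:0005635", "GO:0014069", "GO:0043226"],
        ["part_of(CL:0000312)", "part_of(CL:0000740)", "part_of(CL:0000127)",
         "part_of(UBERON:0002082)", f"part_of({GLIAL_CELL})", "", ""],
    ),
}

_RANDOM_SOURCES = [
    ("PomBase", "SPAC{}.{:02d}", "taxon:4896"),
    ("MGI", "MGI:{}{}", "taxon:10090"),
    ("UniProtKB", "P{}{:02d}", "taxon:9606"),
    ("SGD", "S00000{}{}", "taxon:559292"),
    ("TAIR", "locus:{}{}", "taxon:3702"),
]


def _random_rows(rng: random.Random, count: int) -> list[str]:
    rows = []
    for i in range(count):
        aspect = rng.choice(["F", "P", "C"])
        terms, extensions = _RANDOM_POOLS[aspect]
        db, id_pattern, taxon = rng.choice(_RANDOM_SOURCES)
        oid = id_pattern.format(rng.randint(100, 999), rng.randint(1, 99))
        ext = rng.choice(extensions)
        if rng.random() < 0.1 and ext:
            # occasional disjunction
            ext = ext + "|" + rng.choice([e for e in extensions if e])
        rows.append(
            _gaf_row(db, oid, f"gene{i}", rng.choice(terms), aspect, taxon,
                     evidence=rng.choice(["IDA", "IMP", "IGI"]), extension=ext)
        )
    return rows


def random_ontology(rng: random.Random, n_classes: int = 12) -> Ontology:
    """A random small ontology for reasoner stress tests.

    Classes X:0..X:n-1 get a random acyclic is_a backbone, a few
    relationship axioms over two primitive relations (r1, r2) and a chain
    relation rc = r1 ∘ r2, one or two genus–differentia equivalence axioms,
    and occasionally a disjointness pair.  Aspects are drawn from all four
    buckets so category/range interactions get exercised.
    """
    onto = Ontology()
    aspects = ["biological_process", "cellular_component", "external", "molecular_function"]
    for i in range(n_classes):
        onto.add_term(OntologyTerm(id=f"X:{i}", label=f"class {i}", aspect=rng.choice(aspects)))
    onto.add_relation(RelationDef(label="r1", id="r1",
                                  range_category=rng.choice(["any", "continuant"])))
    onto.add_relation(RelationDef(label="r2", id="r2", range_category="any"))
    onto.add_relation(RelationDef(label="rc", id="rc", chain=("r1", "r2")))

    # acyclic is_a backbone: child index > parent index
    for i in range(1, n_classes):
        for _ in range(rng.randint(0, 2)):
            onto.subclass_axioms.append((f"X:{i}", f"X:{rng.randrange(i)}"))
    for _ in range(rng.randint(1, n_classes // 2)):
        a, b = rng.randrange(n_classes), rng.randrange(n_classes)
        onto.relationship_axioms.append((f"X:{a}", rng.choice(["r1", "r2"]), f"X:{b}"))
    for _ in range(rng.randint(1, 2)):
        defined, genus, filler = rng.sample(range(n_classes), 3)
        onto.equivalence_axioms.append(
            EquivalenceAxiom(f"X:{defined}", f"X:{genus}",
                             ((rng.choice(["r1", "r2"]), f"X:{filler}"),))
        )
    if rng.random() < 0.5:
        a, b = rng.sample(range(n_classes), 2)
        onto.disjointness_axioms.append((f"X:{a}", f"X:{b}"))
    return onto


def generate_fixtures(seed: int = 1, size: str = "small") -> FixtureBundle:
    """Build the deterministic fixture bundle for a seed.

    ``size`` controls only the number of seed-dependent extra corpus rows
    (small: 12, medium: 200); the ontologies and worked examples are fixed.
    """
    if size not in ("small", "medium"):
        raise ValueError(f"size must be 'small' or 'medium', got {size!r}")
    rng = random.Random(seed)
    go, cl, uberon = _mini_go(), _mini_cl(), _mini_uberon()
    relations = builtin_relations()
    registry = IdRegistry(frozenset(REGISTRY_PREFIXES))

    rel_onto = Ontology()
    for rel in relations.values():
        rel_onto.add_relation(rel)

    n_random = 12 if size == "small" else 200
    header = [
        "!gaf-version: 2.0",
        "!generated-by: goext fixtures (synthetic)",
        f"!seed: {seed}",
    ]
    corpus = "\n".join(header + _WORKED_ROWS + _random_rows(rng, n_random)) + "\n"
    invalid = "\n".join(["!gaf-version: 2.0"] + _INVALID_ROWS) + "\n"

    return FixtureBundle(
        go=go, cl=cl, uberon=uberon, relations=relations, registry=registry,
        go_obo=serialize_obo(go, "go-mini"),
        cl_obo=serialize_obo(cl, "cl-mini"),
        uberon_obo=serialize_obo(uberon, "uberon-mini"),
        relations_obo=serialize_obo(rel_onto, "gorel-mini"),
        registry_tsv=registry.to_tsv(REGISTRY_PREFIXES),
        corpus_gaf=corpus,
        invalid_gaf=invalid,
        seed=seed,
        size=size,
    )
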