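"""In-memory ontology model and OBO-subset reader.

The model covers exactly what annotation-extension processing needs: named
terms with a GO aspect, ``is_a`` and relationship axioms, genus–differentia
equivalence axioms (OBO ``intersection_of`` blocks), pairwise disjointness,
and a registry of extension relations with domain/range/usage metadata.

Identifiers are CURIEs in the colon form (``GO:0005635``).  The underscore
form (``GO_0005635``) used in rendered OWL class expressions is accepted on
input and normalized; it is only ever produced by the OWL renderer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

# GO aspects plus a bucket for terms from external ontologies (CL, Uberon, ...)
ASPECTS = ("molecular_function", "biological_process", "cellular_component", "external")

CONTINUANT = "continuant"
OCCURRENT = "occurrent"

_CURIE_RE = re.compile(r"^[A-Za-z_][\w.-]*:[\w.:-]+$")
_UNDERSCORE_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z]+|[A-Za-z]+[0-9]*)_(\d[\w.-]*)$")


class OntologyError(ValueError):
    """Raised for malformed ontology input (duplicate ids, bad stanzas)."""


def normalize_curie(ident: str) -> str:
    """Canonicalize an identifier to the colon CURIE form.

    ``GO_0005635`` -> ``GO:0005635``; colon-form identifiers pass through.
    """
    ident = ident.strip()
    if ":" in ident:
        return ident
    m = _UNDERSCORE_CURIE_RE.match(ident)
    if m:
        return f"{m.group(1)}:{m.group(2)}"
    return ident


def curie_prefix(curie: str) -> str:
    return curie.split(":", 1)[0] if ":" in curie else ""


@dataclass(frozen=True)
class OntologyTerm:
    """A named class: a GO term or a term from a supporting ontology."""

    id: str
    label: str = ""
    aspect: str = "external"
    obsolete: bool = False

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise OntologyError(f"unknown aspect {self.aspect!r} for term {self.id}")


@dataclass(frozen=True)
class RelationDef:
    """An annotation-extension relation.

    ``label`` is the symbol used inside extension fields (``part_of``);
    ``property_id`` is the CURIE of the underlying OWL object property
    (``BFO:0000050`` for part_of) when one is defined.  ``chain`` lists the
    labels of the relations a composite relation abbreviates
    (``regulates_occurs_in`` -> ``[regulates, occurs_in]``).

    Usage metadata mirrors the curation guidance attached to each relation:
    which GO aspects the primary term may come from (``allowed_aspects``),
    which entity identifiers may fill it (``allowed_fillers`` — each entry is
    either a bare ID prefix like ``CL`` or a required-ancestor CURIE), and
    the upper-level category of the filler (``range_category``).
    """

    label: str
    id: str = ""
    property_id: str | None = None
    allowed_aspects: frozenset[str] = frozenset()
    allowed_fillers: frozenset[str] = frozenset()
    range_category: str = "any"  # continuant | occurrent | any
    chain: tuple[str, ...] = ()
    subset_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.chain) == 1:
            raise OntologyError(
                f"relation {self.label}: chain must be empty or have length >= 2"
            )
        if self.range_category not in (CONTINUANT, OCCURRENT, "any"):
            raise OntologyError(
                f"relation {self.label}: bad range category {self.range_category!r}"
            )


@dataclass(frozen=True)
class EquivalenceAxiom:
    """Genus–differentia logical definition: defined ≡ genus ⊓ ∃r1.f1 ⊓ ...

    This is the OBO ``intersection_of`` pattern, e.g. 'glial cell postsynaptic
    density' EquivalentTo 'postsynaptic density' and part_of some 'glial cell'.
    """

    defined_class: str
    genus: str
    differentia: tuple[tuple[str, str], ...]  # (relation label, filler CURIE)

    def __post_init__(self) -> None:
        if not self.differentia:
            raise OntologyError(
                f"equivalence axiom for {self.defined_class}: empty differentia"
            )
        if self.genus == self.defined_class:
            raise OntologyError(
                f"equivalence axiom for {self.defined_class}: genus equals definiendum"
            )


@dataclass
class Ontology:
    """A set of terms plus the axioms reasoning needs.

    ``relationship_axioms`` entries (child, relation label, filler) mean
    child ⊑ ∃r.filler.  ``disjointness_axioms`` pairs mean the intersection
    of the two classes is unsatisfiable.  ``category_assignments`` maps a
    term to its upper-ontology category (continuant/occurrent), used to
    enforce relation range constraints.
    """

    name: str = "ontology"
    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    relations: dict[str, RelationDef] = field(default_factory=dict)
    subclass_axioms: list[tuple[str, str]] = field(default_factory=list)
    relationship_axioms: list[tuple[str, str, str]] = field(default_factory=list)
    equivalence_axioms: list[EquivalenceAxiom] = field(default_factory=list)
    disjointness_axioms: list[tuple[str, str]] = field(default_factory=list)
    category_assignments: dict[str, str] = field(default_factory=dict)

    def add_term(self, term: OntologyTerm) -> None:
        if term.id in self.terms:
            raise OntologyError(f"duplicate term id {term.id}")
        self.terms[term.id] = term

    def add_relation(self, rel: RelationDef) -> None:
        if rel.label in self.relations:
            raise OntologyError(f"duplicate relation label {rel.label}")
        self.relations[rel.label] = rel

    def merge(self, other: "Ontology") -> "Ontology":
        """Union of two ontologies (terms, relations and axioms)."""
        out = self.copy()
        for t in other.terms.values():
            if t.id not in out.terms:
                out.terms[t.id] = t
        for r in other.relations.values():
            if r.label not in out.relations:
                out.relations[r.label] = r
        out.subclass_axioms += [a for a in other.subclass_axioms if a not in out.subclass_axioms]
        out.relationship_axioms += [
            a for a in other.relationship_axioms if a not in out.relationship_axioms
        ]
        out.equivalence_axioms += [
            a for a in other.equivalence_axioms if a not in out.equivalence_axioms
        ]
        out.disjointness_axioms += [
            a for a in other.disjointness_axioms if a not in out.disjointness_axioms
        ]
        out.category_assignments.update(other.category_assignments)
        return out

    def copy(self) -> "Ontology":
        return Ontology(
            name=self.name,
            terms=dict(self.terms),
            relations=dict(self.relations),
            subclass_axioms=list(self.subclass_axioms),
            relationship_axioms=list(self.relationship_axioms),
            equivalence_axioms=list(self.equivalence_axioms),
            disjointness_axioms=list(self.disjointness_axioms),
            category_assignments=dict(self.category_assignments),
        )

    def aspect_of(self, curie: str) -> str:
        term = self.terms.get(curie)
        return term.aspect if term else "external"

    def category_of(self, curie: str) -> str | None:
        """Upper-ontology category of a term.

        Explicit assignments win; otherwise GO biological_process and
        molecular_function terms are occurrents, cellular_component and
        external-ontology terms (cells, anatomy, chemicals) continuants.
        """
        if curie in self.category_assignments:
            return self.category_assignments[curie]
        term = self.terms.get(curie)
        if term is None:
            return None
        if term.aspect in ("biological_process", "molecular_function"):
            return OCCURRENT
        return CONTINUANT

    def equivalence_axioms_for(self, curie: str) -> list[EquivalenceAxiom]:
        return [ax for ax in self.equivalence_axioms if ax.defined_class == curie]

    def dangling_ids(self) -> set[str]:
        """Axiom endpoints that do not resolve to a declared term."""
        mentioned: set[str] = set()
        for c, p in self.subclass_axioms:
            mentioned.update((c, p))
        for c, _, f in self.relationship_axioms:
            mentioned.update((c, f))
        for ax in self.equivalence_axioms:
            mentioned.add(ax.defined_class)
            mentioned.add(ax.genus)
            mentioned.update(f for _, f in ax.differentia)
        for a, b in self.disjointness_axioms:
            mentioned.update((a, b))
        return mentioned - set(self.terms)


@dataclass(frozen=True)
class IdRegistry:
    """The database-abbreviation registry: the set of legal entity ID prefixes.

    Matching is exact and case-sensitive (``CL`` is registered, ``cl`` is not).
    """

    prefixes: frozenset[str]

    def __contains__(self, prefix: str) -> bool:
        return prefix in self.prefixes

    @classmethod
    def from_tsv(cls, text: str) -> "IdRegistry":
        """Read a two-column (prefix, description) TSV; '#'/'!' lines are comments."""
        prefixes = set()
        for line in text.splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            prefixes.add(line.split("\t", 1)[0].strip())
        return cls(frozenset(prefixes))

    def to_tsv(self, descriptions: dict[str, str] | None = None) -> str:
        descriptions = descriptions or {}
        rows = [f"{p}\t{descriptions.get(p, '')}" for p in sorted(self.prefixes)]
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# OBO flat-file subset reader / writer
# ---------------------------------------------------------------------------

_SUPPORTED_TERM_TAGS = {
    "id", "name", "namespace", "is_a", "relationship", "intersection_of",
    "is_obsolete", "subset", "disjoint_from",
}
_SUPPORTED_TYPEDEF_TAGS = {
    "id", "name", "namespace", "domain", "range", "holds_over_chain",
    "subset", "is_obsolete",
}

_NAMESPACE_TO_ASPECT = {
    "molecular_function": "molecular_function",
    "biological_process": "biological_process",
    "cellular_component": "cellular_component",
}


def _strip_obo_comment(value: str) -> str:
    # trailing "! ..." comments; OBO escapes are out of scope for the subset
    idx = value.find("!")
    if idx >= 0:
        value = value[:idx]
    return value.strip()


def _iter_stanzas(text: str) -> Iterator[tuple[str, list[tuple[str, str]]]]:
    kind: str | None = None
    tags: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            if kind is not None:
                yield kind, tags
            kind, tags = line.strip("[]"), []
            continue
        if kind is None:
            continue  # header block (format-version etc.)
        if ":" not in line:
            continue
        tag, value = line.split(":", 1)
        tags.append((tag.strip(), _strip_obo_comment(value)))
    if kind is not None:
        yield kind, tags


def parse_obo(text: str) -> Ontology:
    """Parse the supported OBO subset into an :class:`Ontology`.

    ``[Term]`` stanzas honor id, name, namespace, is_a, relationship,
    intersection_of, is_obsolete, subset and disjoint_from; ``[Typedef]``
    stanzas honor id, name, domain, range, holds_over_chain and subset.
    Anything else is ignored with a logged warning, never an error.

    Each intersection_of block (one bare genus plus at least one
    relation-qualified clause) becomes one :class:`EquivalenceAxiom`.
    """
    onto = Ontology()
    warned_tags: set[str] = set()
    for line in text.splitlines():
        if line.startswith("["):
            break
        if line.startswith("ontology:"):
            onto.name = line.split(":", 1)[1].strip()

    for kind, tags in _iter_stanzas(text):
        if kind == "Term":
            _read_term_stanza(onto, tags, warned_tags)
        elif kind == "Typedef":
            _read_typedef_stanza(onto, tags, warned_tags)
        else:
            if kind not in warned_tags:
                logger.warning("ignoring unsupported stanza type [%s]", kind)
                warned_tags.add(kind)
    return onto


def _read_term_stanza(onto: Ontology, tags: list[tuple[str, str]], warned: set[str]) -> None:
    term_id = ""
    name = ""
    aspect = "external"
    obsolete = False
    is_a: list[str] = []
    rels: list[tuple[str, str]] = []
    inter: list[str] = []
    disjoint: list[str] = []

    for tag, value in tags:
        if tag == "id":
            term_id = normalize_curie(value)
        elif tag == "name":
            name = value
        elif tag == "namespace":
            aspect = _NAMESPACE_TO_ASPECT.get(value, "external")
        elif tag == "is_a":
            is_a.append(normalize_curie(value))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) >= 2:
                rels.append((parts[0], normalize_curie(parts[1])))
        elif tag == "intersection_of":
            inter.append(value)
        elif tag == "is_obsolete":
            obsolete = value.lower() == "true"
        elif tag == "disjoint_from":
            disjoint.append(normalize_curie(value))
        elif tag == "subset":
            pass  # carried for typedefs only; harmless on terms
        elif tag not in _SUPPORTED_TERM_TAGS:
            if tag not in warned:
                logger.warning("ignoring unsupported OBO tag %r", tag)
                warned.add(tag)

    if not term_id:
        raise OntologyError("[Term] stanza without an id")
    onto.add_term(OntologyTerm(id=term_id, label=name, aspect=aspect, obsolete=obsolete))
    for parent in is_a:
        onto.subclass_axioms.append((term_id, parent))
    for rel, filler in rels:
        onto.relationship_axioms.append((term_id, rel, filler))
    for other in disjoint:
        onto.disjointness_axioms.append((term_id, other))
    if inter:
        onto.equivalence_axioms.append(_intersection_to_axiom(term_id, inter))


def _intersection_to_axiom(term_id: str, clauses: list[str]) -> EquivalenceAxiom:
    genus: str | None = None
    differentia: list[tuple[str, str]] = []
    for clause in clauses:
        parts = clause.split()
        if len(parts) == 1:
            if genus is not None:
                raise OntologyError(
                    f"stanza {term_id}: intersection_of has more than one genus"
                )
            genus = normalize_curie(parts[0])
        elif len(parts) == 2:
            differentia.append((parts[0], normalize_curie(parts[1])))
        else:
            raise OntologyError(f"stanza {term_id}: bad intersection_of clause {clause!r}")
    if genus is None:
        raise OntologyError(f"stanza {term_id}: intersection_of with no genus")
    if not differentia:
        raise OntologyError(f"stanza {term_id}: intersection_of with no differentia")
    return EquivalenceAxiom(term_id, genus, tuple(differentia))


def _read_typedef_stanza(onto: Ontology, tags: list[tuple[str, str]], warned: set[str]) -> None:
    ident = ""
    name = ""
    aspects: set[str] = set()
    fillers: set[str] = set()
    range_category = "any"
    chain: tuple[str, ...] = ()
    subsets: set[str] = set()

    for tag, value in tags:
        if tag == "id":
            ident = value
        elif tag == "name":
            name = value
        elif tag == "domain":
            if value in _NAMESPACE_TO_ASPECT:
                aspects.add(value)
        elif tag == "range":
            if value in (CONTINUANT, OCCURRENT):
                range_category = value
            else:
                fillers.add(normalize_curie(value) if "_" in value or ":" in value else value)
        elif tag == "holds_over_chain":
            chain = tuple(value.split())
        elif tag == "subset":
            subsets.add(value)
        elif tag not in _SUPPORTED_TYPEDEF_TAGS:
            if tag not in warned:
                logger.warning("ignoring unsupported OBO tag %r", tag)
                warned.add(tag)

    if not ident:
        raise OntologyError("[Typedef] stanza without an id")
    # Convention: the stanza id is either the underlying property CURIE
    # (id: BFO:0000050 / name: part_of) or the bare relation label itself.
    if ":" in normalize_curie(ident) and not ident.islower():
        property_id: str | None = normalize_curie(ident)
        label = name or ident
    else:
        property_id = None
        label = ident
    onto.add_relation(
        RelationDef(
            label=label,
            id=ident,
            property_id=property_id,
            allowed_aspects=frozenset(aspects),
            allowed_fillers=frozenset(fillers),
            range_category=range_category,
            chain=chain,
            subset_tags=frozenset(subsets),
        )
    )


def serialize_obo(onto: Ontology, ontology_name: str | None = None) -> str:
    """Write the supported OBO subset back out (used for fixture round trips)."""
    out: list[str] = ["format-version: 1.2", f"ontology: {ontology_name or onto.name}", ""]
    equiv_by_term = {}
    for ax in onto.equivalence_axioms:
        equiv_by_term.setdefault(ax.defined_class, ax)
    for term in onto.terms.values():
        out.append("[Term]")
        out.append(f"id: {term.id}")
        if term.label:
            out.append(f"name: {term.label}")
        if term.aspect != "external":
            out.append(f"namespace: {term.aspect}")
        for child, parent in onto.subclass_axioms:
            if child == term.id:
                out.append(f"is_a: {parent}")
        for child, rel, filler in onto.relationship_axioms:
            if child == term.id:
                out.append(f"relationship: {rel} {filler}")
        ax = equiv_by_term.get(term.id)
        if ax is not None:
            out.append(f"intersection_of: {ax.genus}")
            for rel, filler in ax.differentia:
                out.append(f"intersection_of: {rel} {filler}")
        for a, b in onto.disjointness_axioms:
            if a == term.id:
                out.append(f"disjoint_from: {b}")
        if term.obsolete:
            out.append("is_obsolete: true")
        out.append("")
    for rel in onto.relations.values():
        out.append("[Typedef]")
        out.append(f"id: {rel.property_id or rel.label}")
        out.append(f"name: {rel.label}")
        for aspect in sorted(rel.allowed_aspects):
            out.append(f"domain: {aspect}")
        if rel.range_category != "any":
            out.append(f"range: {rel.range_category}")
        for f in sorted(rel.allowed_fillers):
            out.append(f"range: {f}")
        if rel.chain:
            out.append(f"holds_over_chain: {' '.join(rel.chain)}")
        for s in sorted(rel.subset_tags):
            out.append(f"subset: {s}")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Built-in extension relations
# ---------------------------------------------------------------------------

_GENE_PRODUCT_PREFIXES = frozenset(
    {"UniProtKB", "PomBase", "SGD", "MGI", "RGD", "WB", "FB", "TAIR", "dictyBase", "CHEBI"}
)
_CONTEXT_PREFIXES = frozenset({"CL", "UBERON", "PO", "WBbt", "GO", "EMAPA"})
_MF_BP = frozenset({"molecular_function", "biological_process"})
_ALL_ASPECTS = frozenset({"molecular_function", "biological_process", "cellular_component"})


def builtin_relations() -> dict[str, RelationDef]:
    """The most commonly used annotation-extension relations, keyed by label.

    Contextual relations (part_of, occurs_in, happens_during) take cell,
    anatomy, stage or GO terms; molecular relations (has_input,
    has_direct_input, has_regulation_target) take genes, gene products or
    chemicals.  regulates_occurs_in is a composite defined by the property
    chain regulates ∘ occurs_in.
    """
    rels = [
        RelationDef(
            label="part_of", id="part_of", property_id="BFO:0000050",
            allowed_aspects=_ALL_ASPECTS, allowed_fillers=_CONTEXT_PREFIXES,
            range_category="any", subset_tags=frozenset({"contextual"}),
        ),
        RelationDef(
            label="occurs_in", id="occurs_in", property_id="BFO:0000066",
            allowed_aspects=_MF_BP, allowed_fillers=_CONTEXT_PREFIXES,
            range_category=CONTINUANT, subset_tags=frozenset({"contextual"}),
        ),
        RelationDef(
            label="happens_during", id="happens_during", property_id="RO:0002092",
            allowed_aspects=_MF_BP, allowed_fillers=frozenset({"GO"}),
            range_category=OCCURRENT, subset_tags=frozenset({"contextual"}),
        ),
        RelationDef(
            label="exists_during", id="exists_during", property_id=None,
            allowed_aspects=frozenset({"cellular_component"}),
            allowed_fillers=frozenset({"GO"}),
            range_category=OCCURRENT, subset_tags=frozenset({"contextual"}),
        ),
        RelationDef(
            label="has_regulation_target", id="has_regulation_target", property_id=None,
            allowed_aspects=_MF_BP, allowed_fillers=_GENE_PRODUCT_PREFIXES,
            range_category=CONTINUANT, subset_tags=frozenset({"molecular"}),
        ),
        RelationDef(
            label="has_input", id="has_input", property_id="RO:0002233",
            allowed_aspects=_MF_BP, allowed_fillers=_GENE_PRODUCT_PREFIXES,
            range_category=CONTINUANT, subset_tags=frozenset({"molecular"}),
        ),
        RelationDef(
            label="has_direct_input", id="has_direct_input", property_id=None,
            allowed_aspects=_MF_BP, allowed_fillers=_GENE_PRODUCT_PREFIXES,
            range_category=CONTINUANT, subset_tags=frozenset({"molecular"}),
        ),
        RelationDef(
            label="has_output", id="has_output", property_id="RO:0002234",
            allowed_aspects=_MF_BP, allowed_fillers=_GENE_PRODUCT_PREFIXES,
            range_category=CONTINUANT, subset_tags=frozenset({"molecular"}),
        ),
        RelationDef(
            label="regulates", id="regulates", property_id="RO:0002211",
            allowed_aspects=_MF_BP, allowed_fillers=frozenset({"GO"}),
            range_category=OCCURRENT, subset_tags=frozenset({"contextual"}),
        ),
        RelationDef(
            label="regulates_occurs_in", id="regulates_occurs_in", property_id=None,
            allowed_aspects=_MF_BP, allowed_fillers=_CONTEXT_PREFIXES,
            range_category=CONTINUANT, chain=("regulates", "occurs_in"),
            subset_tags=frozenset({"contextual"}),
        ),
    ]
    return {r.label: r for r in rels}


def as_relation_map(
    relations: "dict[str, RelationDef] | Iterable[RelationDef] | Ontology | None",
) -> dict[str, RelationDef]:
    """Accept a dict, an iterable, an Ontology or None (-> builtins)."""
    if relations is None:
        return builtin_relations()
    if isinstance(relations, Ontology):
        return dict(relations.relations)
    if isinstance(relations, dict):
        return relations
    return {r.label: r for r in relations}
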