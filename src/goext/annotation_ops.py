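"""Folding, unfolding, validation and deepening of extended annotations.

*Folding* rewrites each extended annotation (term t, extension e) as a
basic annotation to a freshly materialized application-ontology term
t^A ≡ t ⊓ e, then classifies the application ontology so every folded
term sits under its entailed named superclasses.  *Unfolding* is the
inverse: an annotation to a logically defined term t ≡ t' ⊓ e becomes an
annotation to the genus t' with e in the extension field.  The two
directions are logically equivalent views of the same content.

*Validation* checks extension fields against the relation registry and
the ontologies — grammar, relation existence, entity prefixes, usage
(domain aspect / filler) constraints, and satisfiability by reasoning.
*Deepening* moves an annotation down to the Most Specific Class entailed
for its translated expression.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

from . import el_reasoner
from .el_reasoner import UnsatisfiableExpressionError
from .extension_syntax import (
    AnnotationRecord,
    EMPTY_EXTENSION,
    ExtensionConjunction,
    ExtensionField,
    RelationalExpression,
    split_disjunction,
)
from .ontology_model import (
    EquivalenceAxiom,
    IdRegistry,
    Ontology,
    OntologyTerm,
    RelationDef,
    as_relation_map,
    curie_prefix,
)
from .owl_mapping import conjunction_to_class_expression

logger = logging.getLogger(__name__)

FOLDED_PREFIX = "GOTEMP"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

RULES = ("GRAMMAR", "UNKNOWN_RELATION", "PREFIX", "USAGE_ASPECT", "USAGE_FILLER",
         "UNSATISFIABLE", "DUPLICATE")
_RULE_ORDER = {r: i for i, r in enumerate(RULES)}

# hard logical incoherence and registry breaches are errors; curation-guideline
# breaches are warnings
_SEVERITY = {
    "GRAMMAR": "error",
    "UNKNOWN_RELATION": "error",
    "PREFIX": "error",
    "USAGE_ASPECT": "warning",
    "USAGE_FILLER": "warning",
    "UNSATISFIABLE": "error",
    "DUPLICATE": "warning",
}


@dataclass(frozen=True)
class ValidationEntry:
    record_locator: str
    rule: str
    severity: str
    message: str


@dataclass
class ValidationReport:
    entries: list[ValidationEntry] = field(default_factory=list)

    def add(self, locator: str, rule: str, message: str) -> None:
        self.entries.append(ValidationEntry(locator, rule, _SEVERITY[rule], message))

    @property
    def errors(self) -> list[ValidationEntry]:
        return [e for e in self.entries if e.severity == "error"]

    @property
    def warnings(self) -> list[ValidationEntry]:
        return [e for e in self.entries if e.severity == "warning"]

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self) -> str:
        out = ["locator\trule\tseverity\tmessage"]
        for e in self.entries:
            out.append(f"{e.record_locator}\t{e.rule}\t{e.severity}\t{e.message}")
        return "\n".join(out) + "\n"


def _locator(record: AnnotationRecord, index: int) -> str:
    return f"{index}:{record.gene_product_id}:{record.go_term}"


def validate(
    records: list[AnnotationRecord],
    ontology: Ontology,
    relations: dict[str, RelationDef] | None = None,
    registry: IdRegistry | None = None,
) -> ValidationReport:
    """Check every record's extension; findings are report entries, never raises.

    Checks run in a fixed order per record: grammar well-formedness,
    relation existence, entity prefix membership in the registry, usage
    constraints (primary-term aspect and filler), satisfiability of the
    translated class expression, and duplicate expressions.
    """
    rel_map = as_relation_map(relations if relations is not None else ontology.relations or None)
    report = ValidationReport()
    findings: list[tuple[int, int, ValidationEntry]] = []
    base_index: el_reasoner.SubsumptionIndex | None = None

    def get_base_index() -> el_reasoner.SubsumptionIndex:
        nonlocal base_index
        if base_index is None:
            base_index = el_reasoner.classify(ontology)
        return base_index

    # (record idx, conjunction, query name) pairs needing a satisfiability check
    sat_queries: dict[str, object] = {}
    sat_requests: list[tuple[int, str, str]] = []

    for idx, record in enumerate(records):
        entries: list[tuple[str, str]] = []
        record_aspect = ontology.aspect_of(record.go_term)
        for cidx, conj in enumerate(record.extension.conjunctions):
            seen: set[tuple[str, str]] = set()
            translatable = True
            for expr in conj.expressions:
                if not expr.is_well_formed():
                    entries.append(("GRAMMAR", f"malformed expression {expr}"))
                    translatable = False
                    continue
                rel = rel_map.get(expr.relation)
                if rel is None:
                    entries.append(
                        ("UNKNOWN_RELATION", f"unknown relation {expr.relation!r}")
                    )
                    translatable = False
                elif registry is not None and expr.entity_prefix not in registry:
                    entries.append(
                        ("PREFIX", f"entity prefix {expr.entity_prefix!r} not in registry")
                    )
                if rel is not None:
                    if rel.allowed_aspects and record_aspect not in rel.allowed_aspects:
                        entries.append(
                            (
                                "USAGE_ASPECT",
                                f"{expr.relation} not usable with {record_aspect} term "
                                f"{record.go_term}",
                            )
                        )
                    if rel.allowed_fillers and not _filler_allowed(expr, rel, get_base_index):
                        entries.append(
                            ("USAGE_FILLER", f"filler {expr.entity} not allowed for {expr.relation}")
                        )
                key = (expr.relation, expr.entity)
                if key in seen:
                    entries.append(("DUPLICATE", f"duplicate expression {expr}"))
                seen.add(key)
            if translatable and conj.expressions:
                qname = f"{el_reasoner.QUERY_PREFIX}:v{idx}.{cidx}"
                sat_queries[qname] = conjunction_to_class_expression(
                    record.go_term, conj, rel_map
                )
                sat_requests.append((idx, qname, f"{record.go_term} + {conj}"))
        loc = _locator(records[idx], idx)
        for rule, message in entries:
            findings.append(
                (idx, _RULE_ORDER[rule], ValidationEntry(loc, rule, _SEVERITY[rule], message))
            )

    if sat_requests:
        # one classification answers all satisfiability queries
        gcis: list[el_reasoner.SubClassOf] = []
        for qname, expr in sat_queries.items():
            gcis += el_reasoner._query_gcis(qname, expr)
        index = el_reasoner.classify(ontology, gcis)
        for idx, qname, desc in sat_requests:
            if qname in index.unsatisfiable:
                loc = _locator(records[idx], idx)
                findings.append(
                    (
                        idx,
                        _RULE_ORDER["UNSATISFIABLE"],
                        ValidationEntry(
                            loc, "UNSATISFIABLE", "error",
                            f"expression {desc} is unsatisfiable",
                        ),
                    )
                )

    findings.sort(key=lambda t: (t[0], t[1]))
    report.entries = [entry for _, _, entry in findings]
    return report


def _filler_allowed(expr: RelationalExpression, rel: RelationDef, get_index) -> bool:
    prefix = expr.entity_prefix
    for constraint in rel.allowed_fillers:
        if ":" not in constraint:
            if prefix == constraint:
                return True
        else:
            # required-ancestor constraint: filler must sit below the class
            if get_index().is_subsumed(expr.entity, constraint):
                return True
    return False


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldedTerm:
    """A materialized application-ontology term t^A ≡ t ⊓ e."""

    id: str
    source_term: str
    expression: ExtensionConjunction
    label: str


@dataclass
class FoldResult:
    application_ontology: Ontology
    records: list[AnnotationRecord]
    mapping: dict[str, FoldedTerm]
    unsatisfiable: set[str] = field(default_factory=set)
    report: ValidationReport = field(default_factory=ValidationReport)
    disjunctions_split: int = 0


def folded_term_id(go_term: str, conj: ExtensionConjunction, prefix: str = FOLDED_PREFIX) -> str:
    """Content-addressed folded-term id.

    The id is a stable hash of the source term plus the expression
    canonicalized as a sorted set, so repeated runs and merged corpora
    assign the same id to the same meaning.
    """
    canonical = go_term + "|" + ",".join(sorted(f"{r}({e})" for r, e in conj.as_pairs()))
    digest = hashlib.sha256(canonical.encode()).hexdigest()[:10]
    return f"{prefix}:{digest}"


def fold(
    records: list[AnnotationRecord],
    ontology: Ontology,
    relations: dict[str, RelationDef] | None = None,
) -> FoldResult:
    """Fold extended annotations into basic annotations to materialized terms.

    Disjunctive extensions are split first (one record per conjunction).
    Each distinct (term, expression-as-set) pair materializes one folded
    term with an equivalence axiom; the application ontology is then
    classified so folded terms acquire their entailed named parents (at
    minimum the source term).  Unextended and NOT-qualified records pass
    through unchanged; records whose extension uses an undefined relation
    pass through with an error entry.
    """
    rel_map = as_relation_map(relations)
    app = ontology.copy()
    for rel in rel_map.values():
        if rel.label not in app.relations:
            app.relations[rel.label] = rel

    result = FoldResult(application_ontology=app, records=[], mapping={})
    split_records: list[AnnotationRecord] = []
    for record in records:
        parts = split_disjunction(record)
        if len(parts) > 1:
            result.disjunctions_split += 1
        split_records.extend(parts)

    by_key: dict[tuple[str, frozenset[tuple[str, str]]], FoldedTerm] = {}
    out_records: list[AnnotationRecord] = []
    for idx, record in enumerate(split_records):
        loc = _locator(record, idx)
        if not record.extension.is_extended:
            out_records.append(record)
            continue
        if record.is_negated:
            result.report.entries.append(
                ValidationEntry(loc, "GRAMMAR", "warning",
                                "NOT-qualified record excluded from folding")
            )
            out_records.append(record)
            continue
        conj = record.extension.conjunctions[0]
        unknown = [e.relation for e in conj.expressions if e.relation not in rel_map]
        if unknown:
            result.report.entries.append(
                ValidationEntry(loc, "UNKNOWN_RELATION", "error",
                                f"unknown relation(s) {unknown}; record not folded")
            )
            out_records.append(record)
            continue
        key = (record.go_term, frozenset(conj.as_pairs()))
        folded = by_key.get(key)
        if folded is None:
            folded = _materialize(app, record.go_term, conj, ontology)
            by_key[key] = folded
            result.mapping[folded.id] = folded
        out_records.append(record.with_term(folded.id).with_extension(EMPTY_EXTENSION))

    # classify and attach inferred named parents to the folded terms
    if by_key:
        index = el_reasoner.classify(app)
        existing = set(app.subclass_axioms)
        for folded in by_key.values():
            if folded.id in index.unsatisfiable:
                result.unsatisfiable.add(folded.id)
                result.report.entries.append(
                    ValidationEntry(folded.id, "UNSATISFIABLE", "error",
                                    f"folded term for {folded.source_term} + "
                                    f"{folded.expression} is unsatisfiable")
                )
                continue
            parents = index.named_subsumers(folded.id) - {folded.id}
            parents = {p for p in parents if p in app.terms}
            for p in _direct_parents(parents, index):
                if (folded.id, p) not in existing:
                    app.subclass_axioms.append((folded.id, p))
                    existing.add((folded.id, p))

    result.records = out_records
    return result


def _materialize(
    app: Ontology, go_term: str, conj: ExtensionConjunction, source: Ontology
) -> FoldedTerm:
    term_id = folded_term_id(go_term, conj)
    source_term = source.terms.get(go_term)
    source_label = source_term.label if source_term else go_term
    details = ", ".join(
        f"{e.relation} {_label_of(source, e.entity)}" for e in conj.expressions
    )
    label = f"{source_label} [{details}]"
    aspect = source_term.aspect if source_term else "external"
    if term_id not in app.terms:
        app.add_term(OntologyTerm(id=term_id, label=label, aspect=aspect))
        app.equivalence_axioms.append(
            EquivalenceAxiom(term_id, go_term, conj.as_pairs())
        )
    return FoldedTerm(id=term_id, source_term=go_term, expression=conj, label=label)


def _label_of(onto: Ontology, curie: str) -> str:
    term = onto.terms.get(curie)
    return term.label if term and term.label else curie


def _direct_parents(parents: set[str], index: el_reasoner.SubsumptionIndex) -> set[str]:
    """Transitive reduction: keep only parents with no other parent below them."""
    direct = set()
    for p in parents:
        below = any(
            q != p and index.is_subsumed(q, p) and not index.is_subsumed(p, q)
            for q in parents
        )
        if not below:
            direct.add(p)
    return direct


# ---------------------------------------------------------------------------
# Unfolding
# ---------------------------------------------------------------------------

def unfold(
    records: list[AnnotationRecord],
    ontology: Ontology,
    relations: dict[str, RelationDef] | None = None,
    recursive: bool = False,
) -> tuple[list[AnnotationRecord], ValidationReport]:
    """Rewrite annotations to logically defined terms as extended annotations.

    A record on term t with an equivalence axiom t ≡ t' ⊓ e — t' a
    GO-prefixed term of the same aspect and e inside the extension profile
    — is rewritten to t' with e merged conjunctively into any existing
    extension.  Single-step by default; ``recursive=True`` iterates to a
    fixed point.  Terms with multiple eligible axioms use the first in
    ontology order, with a warning.
    """
    rel_map = as_relation_map(relations)
    report = ValidationReport()
    out = []
    for idx, record in enumerate(records):
        current = record
        seen_terms = {current.go_term}
        while True:
            rewritten = _unfold_once(current, ontology, rel_map, report, idx)
            if rewritten is None:
                break
            current = rewritten
            if not recursive or current.go_term in seen_terms:
                break
            seen_terms.add(current.go_term)
        out.append(current)
    return out, report


def _eligible_axioms(term: str, ontology: Ontology, rel_map: dict[str, RelationDef]):
    eligible = []
    aspect = ontology.aspect_of(term)
    for ax in ontology.equivalence_axioms_for(term):
        if not ax.genus.startswith("GO:"):
            continue
        if ontology.aspect_of(ax.genus) != aspect:
            continue
        if any(r not in rel_map for r, _ in ax.differentia):
            continue
        eligible.append(ax)
    return eligible


def _unfold_once(record, ontology, rel_map, report, idx):
    eligible = _eligible_axioms(record.go_term, ontology, rel_map)
    if not eligible:
        return None
    if len(eligible) > 1:
        report.entries.append(
            ValidationEntry(_locator(record, idx), "GRAMMAR", "warning",
                            f"{record.go_term} has {len(eligible)} eligible equivalence "
                            "axioms; using the first")
        )
    ax = eligible[0]
    differentia = tuple(RelationalExpression(r, f) for r, f in ax.differentia)
    if record.extension.is_extended:
        conjunctions = tuple(
            ExtensionConjunction(conj.expressions + differentia)
            for conj in record.extension.conjunctions
        )
    else:
        conjunctions = (ExtensionConjunction(differentia),)
    return record.with_term(ax.genus).with_extension(ExtensionField(conjunctions))


# ---------------------------------------------------------------------------
# Deepening
# ---------------------------------------------------------------------------

def deepen(
    record: AnnotationRecord,
    ontology: Ontology,
    relations: dict[str, RelationDef] | None = None,
) -> AnnotationRecord:
    """Move an annotation down to the Most Specific Class of its expression.

    If the translated expression t ⊓ e has a unique MSC strictly below t,
    the record's term is replaced by it.  When the MSC is logically
    equivalent to the whole expression, the extension (now redundant) is
    dropped; otherwise it is retained unchanged.  Ties between incomparable
    minima, NOT-qualified records, disjunctive extensions and unextended
    records leave the record as is.
    """
    rel_map = as_relation_map(relations)
    if not record.extension.is_extended or record.is_negated:
        return record
    if len(record.extension.conjunctions) > 1:
        logger.info("deepen: disjunctive extension on %s left unchanged", record.go_term)
        return record
    conj = record.extension.conjunctions[0]
    if any(e.relation not in rel_map for e in conj.expressions):
        return record
    expr = conjunction_to_class_expression(record.go_term, conj, rel_map)
    q = f"{el_reasoner.QUERY_PREFIX}:deepen"
    index = el_reasoner.classify(ontology, el_reasoner._query_gcis(q, expr))
    msc = el_reasoner.msc_from_index(index, q, ontology, expr)  # raises if unsatisfiable
    if len(msc) != 1:
        if len(msc) > 1:
            logger.info("deepen: %d incomparable minima for %s, left unchanged",
                        len(msc), record.go_term)
        return record
    (target,) = msc
    if target == record.go_term:
        return record
    if not index.is_subsumed(target, record.go_term):
        return record
    if index.is_subsumed(target, q):
        # the named term captures the full expression: extension is redundant
        return record.with_term(target).with_extension(EMPTY_EXTENSION)
    return record.with_term(target)
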