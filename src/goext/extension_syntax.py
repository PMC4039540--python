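"""The Relation(Entity) extension grammar and GAF/GPAD annotation I/O.

An annotation-extension field is a disjunction (``|``) of conjunctions
(``,``) of relational expressions, each written ``relation(DB:ID)``::

    Field ::= Conj ('|' Conj)*
    Conj  ::= Rel '(' Entity ')' (',' Rel '(' Entity ')')*

Nesting of expressions is not allowed; the parser rejects it with a
character offset.  The field lives in 1-based column 16 of GAF 2.0 files
and column 11 of GPAD files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Iterator, TextIO

from .ontology_model import curie_prefix

GAF_COLUMNS = 17
GAF_EXTENSION_COLUMN = 16  # 1-based
GPAD_COLUMNS = 12
GPAD_EXTENSION_COLUMN = 11  # 1-based


class ExtensionSyntaxError(ValueError):
    """Malformed extension field; carries the character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class GafFormatError(ValueError):
    pass


@dataclass(frozen=True)
class RelationalExpression:
    """One ``relation(entity)`` pair, e.g. ``part_of(CL:0000312)``."""

    relation: str
    entity: str

    def __str__(self) -> str:
        return f"{self.relation}({self.entity})"

    @property
    def entity_prefix(self) -> str:
        return curie_prefix(self.entity)

    def is_well_formed(self) -> bool:
        if not self.relation:
            return False
        parts = self.entity.split(":")
        return len(parts) == 2 and bool(parts[0]) and bool(parts[1])


@dataclass(frozen=True)
class ExtensionConjunction:
    """A comma-separated run of expressions: all hold simultaneously."""

    expressions: tuple[RelationalExpression, ...]

    def __str__(self) -> str:
        return ",".join(str(e) for e in self.expressions)

    def as_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((e.relation, e.entity) for e in self.expressions)


@dataclass(frozen=True)
class ExtensionField:
    """The whole column-16 value: a disjunction of conjunctions.

    An empty field (no conjunctions) is an unextended annotation.
    """

    conjunctions: tuple[ExtensionConjunction, ...] = ()

    def __str__(self) -> str:
        return serialize_extension_field(self)

    def __bool__(self) -> bool:
        return bool(self.conjunctions)

    @property
    def is_extended(self) -> bool:
        return bool(self.conjunctions)


EMPTY_EXTENSION = ExtensionField()

_EXPR_RE = re.compile(r"^\s*([^\s(),|]+)\s*\(\s*([^()]*?)\s*\)\s*$")


def parse_extension_field(text: str) -> ExtensionField:
    """Parse a raw extension-field string.

    Whitespace around separators is tolerated; ``""`` yields the empty
    field.  Unbalanced or nested parentheses, empty conjuncts between
    separators and entities lacking a single ``prefix:id`` colon are
    rejected.
    """
    if text is None or not text.strip():
        return EMPTY_EXTENSION
    _check_parentheses(text)

    conjunctions = []
    for alt in _split_top_level(text, "|"):
        exprs = []
        for chunk in _split_top_level(alt, ","):
            if not chunk.strip():
                raise ExtensionSyntaxError("empty expression between separators")
            m = _EXPR_RE.match(chunk)
            if not m:
                raise ExtensionSyntaxError(f"cannot parse expression {chunk.strip()!r}")
            relation, entity = m.group(1), m.group(2)
            parts = entity.split(":")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ExtensionSyntaxError(
                    f"malformed entity {entity!r} in {chunk.strip()!r}: "
                    "expected DB:ID with exactly one colon"
                )
            exprs.append(RelationalExpression(relation, entity))
        conjunctions.append(ExtensionConjunction(tuple(exprs)))
    return ExtensionField(tuple(conjunctions))


def _check_parentheses(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
            if depth > 1:
                raise ExtensionSyntaxError("nested parentheses are not allowed", i)
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ExtensionSyntaxError("unbalanced ')'", i)
    if depth != 0:
        raise ExtensionSyntaxError("unbalanced '('", len(text))


def _split_top_level(text: str, sep: str) -> list[str]:
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == sep and depth == 0:
            parts.append(text[start:i])
            start = i + 1
    parts.append(text[start:])
    return parts


def serialize_extension_field(fld: ExtensionField) -> str:
    """Canonical text: conjuncts joined by ',', alternatives by '|', no spaces."""
    return "|".join(
        ",".join(str(e) for e in conj.expressions) for conj in fld.conjunctions
    )


# ---------------------------------------------------------------------------
# Annotation records and GAF / GPAD I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-product-to-GO-term association.

    Field names follow GAF 2.0 column order; GPAD-only payloads travel in
    ``properties``.  ``source_columns`` records how many columns the input
    row had (15 for GAF 1.0, 17 for GAF 2.0, 12 for GPAD).
    """

    db: str = ""
    object_id: str = ""
    symbol: str = ""
    qualifier: str = ""
    go_term: str = ""
    reference: str = ""
    evidence_code: str = ""
    with_from: str = ""
    aspect: str = ""
    object_name: str = ""
    synonym: str = ""
    object_type: str = ""
    taxon: str = ""
    date: str = ""
    assigned_by: str = ""
    extension: ExtensionField = EMPTY_EXTENSION
    form_id: str = ""
    interacting_taxon: str = ""
    properties: str = ""
    source_columns: int = GAF_COLUMNS

    @property
    def gene_product_id(self) -> str:
        return f"{self.db}:{self.object_id}"

    @property
    def is_negated(self) -> bool:
        return "NOT" in self.qualifier.split("|")

    def with_extension(self, ext: ExtensionField) -> "AnnotationRecord":
        return replace(self, extension=ext)

    def with_term(self, go_term: str) -> "AnnotationRecord":
        return replace(self, go_term=go_term)


@dataclass(frozen=True)
class RowError:
    """A row-level parse problem; parsing continues past it."""

    line_number: int
    message: str
    line: str = ""


@dataclass
class ParseResult:
    records: list[AnnotationRecord] = dc_field(default_factory=list)
    errors: list[RowError] = dc_field(default_factory=list)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _lines(stream: TextIO | str | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from stream.splitlines()
    else:
        for line in stream:
            yield line.rstrip("\n")


def read_gaf(stream: TextIO | str | Iterable[str]) -> ParseResult:
    """Read GAF rows: 17-column GAF 2.0 (extension in column 16) or
    15-column GAF 1.0 (no extension).  '!'-prefixed lines are comments.

    Rows with fewer than 15 columns or an unparseable extension are
    collected as :class:`RowError` entries and skipped.
    """
    result = ParseResult()
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            result.errors.append(
                RowError(lineno, f"expected >= 15 tab-separated columns, got {len(cols)}", line)
            )
            continue
        try:
            ext = (
                parse_extension_field(cols[GAF_EXTENSION_COLUMN - 1])
                if len(cols) >= GAF_EXTENSION_COLUMN
                else EMPTY_EXTENSION
            )
        except ExtensionSyntaxError as exc:
            result.errors.append(RowError(lineno, f"bad extension field: {exc}", line))
            continue
        result.records.append(
            AnnotationRecord(
                db=cols[0], object_id=cols[1], symbol=cols[2], qualifier=cols[3],
                go_term=cols[4], reference=cols[5], evidence_code=cols[6],
                with_from=cols[7], aspect=cols[8], object_name=cols[9],
                synonym=cols[10], object_type=cols[11], taxon=cols[12],
                date=cols[13], assigned_by=cols[14], extension=ext,
                form_id=cols[16] if len(cols) >= 17 else "",
                source_columns=len(cols),
            )
        )
    return result


def write_gaf(records: Iterable[AnnotationRecord]) -> str:
    """Serialize records as GAF 2.0: 17 columns, extension in column 16."""
    out = ["!gaf-version: 2.0"]
    for r in records:
        out.append(
            "\t".join(
                [
                    r.db, r.object_id, r.symbol, r.qualifier, r.go_term,
                    r.reference, r.evidence_code, r.with_from, r.aspect,
                    r.object_name, r.synonym, r.object_type, r.taxon,
                    r.date, r.assigned_by,
                    serialize_extension_field(r.extension), r.form_id,
                ]
            )
        )
    return "\n".join(out) + "\n"


def read_gpad(stream: TextIO | str | Iterable[str]) -> ParseResult:
    """Read 12-column GPAD rows; the extension sits in column 11."""
    result = ParseResult()
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < GPAD_EXTENSION_COLUMN:
            result.errors.append(
                RowError(lineno, f"expected >= {GPAD_EXTENSION_COLUMN} columns, got {len(cols)}", line)
            )
            continue
        try:
            ext = parse_extension_field(cols[GPAD_EXTENSION_COLUMN - 1])
        except ExtensionSyntaxError as exc:
            result.errors.append(RowError(lineno, f"bad extension field: {exc}", line))
            continue
        result.records.append(
            AnnotationRecord(
                db=cols[0], object_id=cols[1], qualifier=cols[2], go_term=cols[3],
                reference=cols[4], evidence_code=cols[5], with_from=cols[6],
                interacting_taxon=cols[7], date=cols[8], assigned_by=cols[9],
                extension=ext,
                properties=cols[11] if len(cols) >= 12 else "",
                source_columns=len(cols),
            )
        )
    return result


def write_gpad(records: Iterable[AnnotationRecord]) -> str:
    """Serialize records as GPAD: 12 columns, extension in column 11.

    The extension field transfers verbatim from GAF; GAF-only columns
    (symbol, aspect, object name/synonym/type, taxon, form id) have no GPAD
    slot and are dropped.
    """
    out = ["!gpa-version: 1.1"]
    for r in records:
        out.append(
            "\t".join(
                [
                    r.db, r.object_id, r.qualifier, r.go_term, r.reference,
                    r.evidence_code, r.with_from, r.interacting_taxon,
                    r.date, r.assigned_by,
                    serialize_extension_field(r.extension), r.properties,
                ]
            )
        )
    return "\n".join(out) + "\n"


def split_disjunction(record: AnnotationRecord) -> list[AnnotationRecord]:
    """Expand a disjunctive extension into independent annotations.

    A pipe-separated field is equivalent to multiple annotations, one per
    conjunction, all other columns unchanged.  Records with 0 or 1
    conjunctions pass through as a singleton list.
    """
    if len(record.extension.conjunctions) <= 1:
        return [record]
    return [
        record.with_extension(ExtensionField((conj,)))
        for conj in record.extension.conjunctions
    ]


# ---------------------------------------------------------------------------
# Per-taxon extension statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonStats:
    taxon: str
    total: int
    extended: int
    percent: float


def percent_extended(total: int, extended: int) -> float:
    """100·extended/total, rounded half-away-from-zero to one decimal."""
    if total == 0:
        return 0.0
    frac = Decimal(100) * Decimal(extended) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compute_extension_stats(
    records: Iterable[AnnotationRecord],
    taxon_extractor: Callable[[AnnotationRecord], str] | None = None,
) -> list[TaxonStats]:
    """Count total and extended annotations per taxon.

    A record is *extended* when its extension field holds at least one
    conjunction.  Records without a taxon bucket under ``"unknown"``.
    Rows are sorted by extended count (descending), then taxon.
    """
    extract = taxon_extractor or (lambda r: r.taxon)
    totals: dict[str, int] = {}
    extended: dict[str, int] = {}
    for r in records:
        taxon = extract(r) or "unknown"
        totals[taxon] = totals.get(taxon, 0) + 1
        if r.extension.is_extended:
            extended[taxon] = extended.get(taxon, 0) + 1
    rows = [
        TaxonStats(t, totals[t], extended.get(t, 0), percent_extended(totals[t], extended.get(t, 0)))
        for t in totals
    ]
    rows.sort(key=lambda s: (-s.extended, s.taxon))
    return rows


def stats_to_tsv(rows: Iterable[TaxonStats]) -> str:
    out = ["taxon\ttotal\textended\tpercent"]
    for s in rows:
        out.append(f"{s.taxon}\t{s.total}\t{s.extended}\t{s.percent:.1f}")
    return "\n".join(out) + "\n"
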