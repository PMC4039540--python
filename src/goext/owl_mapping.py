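"""Translation between extension conjunctions and EL-profile class expressions.

A conjunctive extension on a GO term t translates to the OWL intersection

    t and (r1 some filler1) and (r2 some filler2) ...

with each relational expression becoming an existential restriction.  A
relation defined by a property chain ``s = r1 ∘ r2`` expands to a nested
existential ``r1 some (r2 some filler)`` and is re-folded to ``s`` on the
way back.  Only EL constructs appear: named classes, intersections and
existential restrictions (plus Bottom for reasoner output).
"""

from __future__ import annotations

from dataclasses import dataclass

from .extension_syntax import ExtensionConjunction, RelationalExpression
from .ontology_model import RelationDef, as_relation_map, normalize_curie


class TranslationError(ValueError):
    pass


class NotExpressibleError(TranslationError):
    """The class expression falls outside the extension profile."""


@dataclass(frozen=True)
class ClassExpression:
    def is_named(self) -> bool:
        return isinstance(self, Named)


@dataclass(frozen=True)
class Named(ClassExpression):
    id: str


@dataclass(frozen=True)
class Bottom(ClassExpression):
    """owl:Nothing — the unsatisfiable class."""


@dataclass(frozen=True)
class SomeValuesFrom(ClassExpression):
    property: str  # property CURIE or relation label
    filler: ClassExpression


@dataclass(frozen=True)
class Intersection(ClassExpression):
    operands: tuple[ClassExpression, ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise TranslationError("intersection requires >= 2 operands")
        if any(isinstance(op, Intersection) for op in self.operands):
            raise TranslationError("intersections must be flattened")


def intersection_of(operands: list[ClassExpression]) -> ClassExpression:
    """Build a flattened intersection; collapses singletons."""
    flat: list[ClassExpression] = []
    for op in operands:
        if isinstance(op, Intersection):
            flat.extend(op.operands)
        else:
            flat.append(op)
    if not flat:
        raise TranslationError("empty intersection")
    if len(flat) == 1:
        return flat[0]
    return Intersection(tuple(flat))


def same_expression(a: ClassExpression, b: ClassExpression) -> bool:
    """Structural equality, order-insensitive over intersection operands."""
    if isinstance(a, Intersection) and isinstance(b, Intersection):
        return _operand_key(a) == _operand_key(b)
    if isinstance(a, SomeValuesFrom) and isinstance(b, SomeValuesFrom):
        return a.property == b.property and same_expression(a.filler, b.filler)
    return a == b


def _operand_key(expr: Intersection) -> frozenset:
    return frozenset(render_owl(op) for op in expr.operands)


def property_ref(rel: RelationDef) -> str:
    """The property CURIE a relation translates to.

    Relations without an assigned object property render under a reserved
    GOREL namespace so translation stays total and invertible.
    """
    return rel.property_id if rel.property_id else f"GOREL:{rel.label}"


def _expression_to_restriction(
    expr: RelationalExpression, relations: dict[str, RelationDef]
) -> SomeValuesFrom:
    rel = relations.get(expr.relation)
    if rel is None:
        raise TranslationError(f"unknown extension relation {expr.relation!r}")
    filler: ClassExpression = Named(normalize_curie(expr.entity))
    if rel.chain:
        if len(rel.chain) != 2:
            raise TranslationError(
                f"relation {rel.label}: only binary property chains are supported"
            )
        inner_label, outer_label = rel.chain[1], rel.chain[0]
        inner = relations.get(inner_label)
        outer = relations.get(outer_label)
        if inner is None or outer is None:
            raise TranslationError(
                f"chain relation {rel.label}: undefined chain element"
            )
        return SomeValuesFrom(property_ref(outer), SomeValuesFrom(property_ref(inner), filler))
    return SomeValuesFrom(property_ref(rel), filler)


def conjunction_to_class_expression(
    go_term: str,
    conj: ExtensionConjunction | None,
    relations: dict[str, RelationDef] | None = None,
) -> ClassExpression:
    """Translate (GO term, conjunctive extension) to a class expression.

    The result is ``Named(go_term)`` for an empty conjunction, otherwise an
    intersection of the named term and one existential restriction per
    relational expression, in input order.
    """
    rel_map = as_relation_map(relations)
    term = Named(normalize_curie(go_term))
    if conj is None or not conj.expressions:
        return term
    operands: list[ClassExpression] = [term]
    for expr in conj.expressions:
        operands.append(_expression_to_restriction(expr, rel_map))
    return Intersection(tuple(operands))


def class_expression_to_conjunction(
    expr: ClassExpression,
    relations: dict[str, RelationDef] | None = None,
) -> tuple[str, ExtensionConjunction]:
    """Invert :func:`conjunction_to_class_expression`.

    Accepts a GO-prefixed named class, or an intersection of exactly one
    GO-prefixed named class plus existential restrictions whose fillers are
    named (or two-deep nests matching a declared chain relation).
    """
    rel_map = as_relation_map(relations)
    by_property = _property_index(rel_map)

    if isinstance(expr, Named):
        if not expr.id.startswith("GO:"):
            raise NotExpressibleError(f"named class {expr.id} is not a GO term")
        return expr.id, ExtensionConjunction(())
    if not isinstance(expr, Intersection):
        raise NotExpressibleError(f"{type(expr).__name__} is not in the extension profile")

    go_terms = [op for op in expr.operands if isinstance(op, Named)]
    if len(go_terms) != 1 or not go_terms[0].id.startswith("GO:"):
        raise NotExpressibleError(
            "extension profile requires exactly one GO-prefixed named operand"
        )
    restrictions = [op for op in expr.operands if isinstance(op, SomeValuesFrom)]
    if len(restrictions) + 1 != len(expr.operands):
        raise NotExpressibleError("operands must be one named class plus restrictions")

    exprs = []
    for r in restrictions:
        exprs.append(_restriction_to_expression(r, rel_map, by_property))
    return go_terms[0].id, ExtensionConjunction(tuple(exprs))


def _property_index(rel_map: dict[str, RelationDef]) -> dict[str, str]:
    # first declaration wins, matching relation-file order
    index: dict[str, str] = {}
    for label, rel in rel_map.items():
        ref = property_ref(rel)
        index.setdefault(ref, label)
    return index


def _restriction_to_expression(
    r: SomeValuesFrom,
    rel_map: dict[str, RelationDef],
    by_property: dict[str, str],
) -> RelationalExpression:
    if isinstance(r.filler, Named):
        label = by_property.get(r.property)
        if label is None:
            raise NotExpressibleError(f"no relation maps to property {r.property}")
        return RelationalExpression(label, r.filler.id)
    if isinstance(r.filler, SomeValuesFrom) and isinstance(r.filler.filler, Named):
        # two-deep nesting: must match a declared binary chain
        outer_label = by_property.get(r.property)
        inner_label = by_property.get(r.filler.property)
        for label, rel in rel_map.items():
            if rel.chain == (outer_label, inner_label):
                return RelationalExpression(label, r.filler.filler.id)
        raise NotExpressibleError(
            f"nested existential {r.property} some ({r.filler.property} some ...) "
            "matches no declared chain relation"
        )
    raise NotExpressibleError("restriction nesting deeper than any declared chain")


def _underscore(curie: str) -> str:
    return curie.replace(":", "_", 1)


def render_owl(expr: ClassExpression) -> str:
    """Canonical Manchester-like text with underscore-form identifiers.

    Intersection operands are joined by " and ", every operand after the
    first parenthesized; existentials render as "P some F" with complex
    fillers parenthesized.
    """
    return _render(expr, top=True)


def _render(expr: ClassExpression, top: bool = False) -> str:
    if isinstance(expr, Named):
        return _underscore(expr.id)
    if isinstance(expr, Bottom):
        return "owl_Nothing"
    if isinstance(expr, SomeValuesFrom):
        filler = _render(expr.filler)
        if not isinstance(expr.filler, (Named, Bottom)):
            filler = f"({filler})"
        return f"{_underscore(expr.property)} some {filler}"
    if isinstance(expr, Intersection):
        parts = []
        for i, op in enumerate(expr.operands):
            text = _render(op)
            # leading Named conjunct stays bare: "GO_0005635 and (...)"
            if i > 0 or not isinstance(op, (Named, Bottom)):
                text = f"({text})"
            parts.append(text)
        return " and ".join(parts)
    raise TranslationError(f"cannot render {expr!r}")
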