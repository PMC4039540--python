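"""A small EL completion reasoner.

Annotation-extension class expressions live inside the EL++ profile
(named classes, intersections, existential restrictions, binary property
chains), so classification is polynomial.  The engine here follows the
standard two-stage recipe: structural *normalization* of general class
inclusions into a handful of normal forms, then *saturation* with the EL
completion rules to a fixed point.  The resulting
:class:`SubsumptionIndex` answers subsumption, satisfiability and
most-specific-class queries.

Relation range constraints are compiled to axioms: each term is placed
under an upper-level Continuant (BFO:0000002) or Occurrent (BFO:0000003)
marker class, the two markers are disjoint, and a relation with a
continuant range contributes ∃r.Occurrent ⊑ ⊥ (symmetrically for
occurrent ranges).  This is what makes ``occurs_in some 'apoptotic
process'`` come out unsatisfiable.

:func:`brute_force_subsumption` is an independent oracle used in tests: a
naive closure over unnormalized expressions, sharing no inference code
with :func:`saturate`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .ontology_model import CONTINUANT, OCCURRENT, Ontology, as_relation_map
from .owl_mapping import (
    Bottom,
    ClassExpression,
    Intersection,
    Named,
    SomeValuesFrom,
    property_ref,
)

BOT = "owl:Nothing"
CONTINUANT_CLASS = "BFO:0000002"
OCCURRENT_CLASS = "BFO:0000003"
FRESH_PREFIX = "__el"
QUERY_PREFIX = "__q"


class ReasonerError(ValueError):
    pass


class UnsatisfiableExpressionError(ReasonerError):
    pass


@dataclass(frozen=True)
class SubClassOf:
    """A general class inclusion C ⊑ D."""

    sub: ClassExpression
    sup: ClassExpression


def is_fresh(name: str) -> bool:
    return name.startswith((FRESH_PREFIX, QUERY_PREFIX))


# ---------------------------------------------------------------------------
# Ontology -> GCIs
# ---------------------------------------------------------------------------

def ontology_axioms(onto: Ontology) -> tuple[list[SubClassOf], list[tuple[str, str, str]]]:
    """Compile an Ontology into (GCIs, binary role chains).

    Roles are identified by property CURIE when the relation declares one
    (so axioms meet translated extension expressions on equal terms) and by
    label otherwise.  Obsolete terms are excluded from reasoning.
    """
    rel_map = as_relation_map(onto)

    def role(label: str) -> str:
        rel = rel_map.get(label)
        return property_ref(rel) if rel is not None else label

    obsolete = {t.id for t in onto.terms.values() if t.obsolete}

    def live(*ids: str) -> bool:
        return not any(i in obsolete for i in ids)

    gcis: list[SubClassOf] = []
    for child, parent in onto.subclass_axioms:
        if live(child, parent):
            gcis.append(SubClassOf(Named(child), Named(parent)))
    for child, rel, filler in onto.relationship_axioms:
        if live(child, filler):
            gcis.append(SubClassOf(Named(child), SomeValuesFrom(role(rel), Named(filler))))
    for ax in onto.equivalence_axioms:
        if not live(ax.defined_class, ax.genus, *(f for _, f in ax.differentia)):
            continue
        operands: list[ClassExpression] = [Named(ax.genus)]
        operands += [SomeValuesFrom(role(r), Named(f)) for r, f in ax.differentia]
        expr = Intersection(tuple(operands))
        gcis.append(SubClassOf(Named(ax.defined_class), expr))
        gcis.append(SubClassOf(expr, Named(ax.defined_class)))
    for a, b in onto.disjointness_axioms:
        if live(a, b):
            gcis.append(SubClassOf(Intersection((Named(a), Named(b))), Bottom()))

    # range constraints, compiled through upper-level category marker classes;
    # categories are only materialized when some relation constrains its range
    range_used = False
    for rel in rel_map.values():
        if rel.chain:
            continue
        if rel.range_category == CONTINUANT:
            gcis.append(SubClassOf(SomeValuesFrom(role(rel.label), Named(OCCURRENT_CLASS)), Bottom()))
            range_used = True
        elif rel.range_category == OCCURRENT:
            gcis.append(SubClassOf(SomeValuesFrom(role(rel.label), Named(CONTINUANT_CLASS)), Bottom()))
            range_used = True
    if range_used:
        for term in onto.terms.values():
            if term.obsolete:
                continue
            cat = onto.category_of(term.id)
            if cat == CONTINUANT:
                gcis.append(SubClassOf(Named(term.id), Named(CONTINUANT_CLASS)))
            elif cat == OCCURRENT:
                gcis.append(SubClassOf(Named(term.id), Named(OCCURRENT_CLASS)))
        gcis.append(
            SubClassOf(Intersection((Named(CONTINUANT_CLASS), Named(OCCURRENT_CLASS))), Bottom())
        )

    chains: list[tuple[str, str, str]] = []
    for rel in rel_map.values():
        if rel.chain:
            if len(rel.chain) != 2:
                raise ReasonerError(
                    f"relation {rel.label}: only binary role chains are supported"
                )
            chains.append((role(rel.chain[0]), role(rel.chain[1]), role(rel.label)))
    return gcis, chains


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedAxiomSet:
    """EL normal forms.

    atomic_subsumptions: A ⊑ B; conjunctions: A1 ⊓ A2 ⊑ B;
    existential_right: A ⊑ ∃r.B; existential_left: ∃r.A ⊑ B;
    role_inclusions: r ⊑ s; role_chains: r1 ∘ r2 ⊑ s.
    Bottom appears as the atom ``owl:Nothing``.
    """

    atomic_subsumptions: list[tuple[str, str]] = field(default_factory=list)
    conjunctions: list[tuple[str, str, str]] = field(default_factory=list)
    existential_right: list[tuple[str, str, str]] = field(default_factory=list)
    existential_left: list[tuple[str, str, str]] = field(default_factory=list)
    role_inclusions: list[tuple[str, str]] = field(default_factory=list)
    role_chains: list[tuple[str, str, str]] = field(default_factory=list)

    def atoms(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.atomic_subsumptions:
            out.update((a, b))
        for a1, a2, b in self.conjunctions:
            out.update((a1, a2, b))
        for a, _, b in self.existential_right:
            out.update((a, b))
        for _, a, b in self.existential_left:
            out.update((a, b))
        return out


def _atom_name(expr: ClassExpression) -> str | None:
    if isinstance(expr, Named):
        return expr.id
    if isinstance(expr, Bottom):
        return BOT
    return None


class _Normalizer:
    def __init__(self) -> None:
        self.out = NormalizedAxiomSet()
        self._counter = itertools.count()
        self._defined: dict[ClassExpression, str] = {}

    def fresh(self) -> str:
        return f"{FRESH_PREFIX}:{next(self._counter)}"

    def name_left(self, expr: ClassExpression) -> str:
        """Fresh A with expr ⊑ A (for complex expressions used on the left)."""
        atom = _atom_name(expr)
        if atom is not None:
            return atom
        a = self.fresh()
        self.add(SubClassOf(expr, Named(a)))
        return a

    def name_right(self, expr: ClassExpression) -> str:
        """Fresh A with A ⊑ expr (for complex expressions used on the right)."""
        atom = _atom_name(expr)
        if atom is not None:
            return atom
        a = self.fresh()
        self.add(SubClassOf(Named(a), expr))
        return a

    def add(self, gci: SubClassOf) -> None:
        sub, sup = gci.sub, gci.sup
        sub_atom, sup_atom = _atom_name(sub), _atom_name(sup)

        if sub_atom == BOT:
            return  # ⊥ ⊑ D is vacuous
        if sub_atom is not None and sup_atom is not None:
            self.out.atomic_subsumptions.append((sub_atom, sup_atom))
            return

        if sub_atom is not None:
            # atomic ⊑ complex
            if isinstance(sup, Intersection):
                for op in sup.operands:
                    self.add(SubClassOf(sub, op))
            elif isinstance(sup, SomeValuesFrom):
                filler = self.name_right(sup.filler)
                self.out.existential_right.append((sub_atom, sup.property, filler))
            else:  # pragma: no cover - exhaustive
                raise ReasonerError(f"non-EL construct {sup!r}")
            return

        if sup_atom is not None:
            # complex ⊑ atomic
            if isinstance(sub, SomeValuesFrom):
                filler = self.name_left(sub.filler)
                self.out.existential_left.append((sub.property, filler, sup_atom))
            elif isinstance(sub, Intersection):
                atoms = [self.name_left(op) for op in sub.operands]
                # fold the n-ary conjunction into binary steps
                acc = atoms[0]
                for nxt in atoms[1:-1]:
                    step = self.fresh()
                    self.out.conjunctions.append((acc, nxt, step))
                    acc = step
                self.out.conjunctions.append((acc, atoms[-1], sup_atom))
            else:  # pragma: no cover
                raise ReasonerError(f"non-EL construct {sub!r}")
            return

        # complex ⊑ complex: split through a fresh middle name
        mid = self.name_left(sub)
        self.add(SubClassOf(Named(mid), sup))


def normalize(
    ontology: Ontology | None = None,
    extra: list[SubClassOf] | tuple[SubClassOf, ...] = (),
) -> NormalizedAxiomSet:
    """Normalize an ontology's axioms (plus extra GCIs) into EL normal forms.

    Fresh names are assigned sequentially in input order, so the output is
    deterministic for a given input.
    """
    norm = _Normalizer()
    chains: list[tuple[str, str, str]] = []
    if ontology is not None:
        gcis, chains = ontology_axioms(ontology)
        for gci in gcis:
            norm.add(gci)
    for gci in extra:
        norm.add(gci)
    norm.out.role_chains.extend(chains)
    return norm.out


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

@dataclass
class SubsumptionIndex:
    """Completion output: per class, its set of named subsumers.

    ``subsumers`` is reflexively and transitively closed; unsatisfiable
    classes carry ``owl:Nothing`` among their subsumers.
    """

    subsumers: dict[str, set[str]]
    unsatisfiable: set[str]

    def is_subsumed(self, sub: str, sup: str) -> bool:
        if sub == sup:
            return True
        if sub in self.unsatisfiable:
            return True
        return sup in self.subsumers.get(sub, set())

    def named_subsumers(self, cls: str, include_fresh: bool = False) -> set[str]:
        out = {s for s in self.subsumers.get(cls, {cls}) if s != BOT}
        if not include_fresh:
            out = {s for s in out if not is_fresh(s)}
        return out

    def to_tsv(self) -> str:
        lines = []
        for cls in sorted(self.subsumers):
            if is_fresh(cls):
                continue
            for sup in sorted(self.subsumers[cls]):
                if sup != cls and not is_fresh(sup):
                    lines.append(f"{cls}\t{sup}")
        return "\n".join(lines) + ("\n" if lines else "")


def saturate(axioms: NormalizedAxiomSet) -> SubsumptionIndex:
    """Run the EL completion rules to a fixed point.

    Maintains S(X) (named subsumers of X) and R(r) (derived role links)
    under the standard rules: told subsumptions, binary conjunctions,
    existential introduction and elimination, role inclusions, binary role
    chains, and bottom propagation along role links.
    """
    atoms = axioms.atoms()
    sub_index: dict[str, list[str]] = {}
    for a, b in axioms.atomic_subsumptions:
        sub_index.setdefault(a, []).append(b)
    conj_index: dict[str, list[tuple[str, str]]] = {}
    for a1, a2, b in axioms.conjunctions:
        conj_index.setdefault(a1, []).append((a2, b))
        if a1 != a2:
            conj_index.setdefault(a2, []).append((a1, b))
    exr_index: dict[str, list[tuple[str, str]]] = {}
    for a, r, b in axioms.existential_right:
        exr_index.setdefault(a, []).append((r, b))
    exl_index: dict[tuple[str, str], list[str]] = {}
    for r, a, b in axioms.existential_left:
        exl_index.setdefault((r, a), []).append(b)
    role_sup: dict[str, list[str]] = {}
    for r, s in axioms.role_inclusions:
        role_sup.setdefault(r, []).append(s)
    chain_first: dict[str, list[tuple[str, str]]] = {}
    chain_second: dict[str, list[tuple[str, str]]] = {}
    for r1, r2, s in axioms.role_chains:
        chain_first.setdefault(r1, []).append((r2, s))
        chain_second.setdefault(r2, []).append((r1, s))

    S: dict[str, set[str]] = {a: {a} for a in atoms}
    links_out: dict[tuple[str, str], set[str]] = {}  # (r, A) -> {B}
    links_in: dict[str, set[tuple[str, str]]] = {}  # B -> {(r, A)}
    work: list[tuple] = [("sub", a, a) for a in atoms]

    def add_sub(x: str, a: str) -> None:
        if x not in S:
            S[x] = {x}
            work.append(("sub", x, x))
        if a not in S[x]:
            S[x].add(a)
            work.append(("sub", x, a))

    def add_link(r: str, a: str, b: str) -> None:
        bucket = links_out.setdefault((r, a), set())
        if b not in bucket:
            bucket.add(b)
            links_in.setdefault(b, set()).add((r, a))
            work.append(("link", r, a, b))

    while work:
        item = work.pop()
        if item[0] == "sub":
            _, x, a = item
            for b in sub_index.get(a, ()):  # told subsumption
                add_sub(x, b)
            for a2, b in conj_index.get(a, ()):  # conjunction
                if a2 in S[x]:
                    add_sub(x, b)
            for r, b in exr_index.get(a, ()):  # existential introduction
                add_link(r, x, b)
            for r, y in links_in.get(x, ()):  # existential elimination on new subsumer
                for b in exl_index.get((r, a), ()):
                    add_sub(y, b)
                if a == BOT:
                    add_sub(y, BOT)
        else:
            _, r, a, b = item
            for x in list(S.get(b, {b})):  # existential elimination
                for c in exl_index.get((r, x), ()):
                    add_sub(a, c)
            if BOT in S.get(b, ()):  # bottom propagation
                add_sub(a, BOT)
            for s in role_sup.get(r, ()):  # role inclusion
                add_link(s, a, b)
            for r2, s in chain_first.get(r, ()):  # chain: this link is first
                for c in links_out.get((r2, b), ()):
                    add_link(s, a, c)
            for r1, s in chain_second.get(r, ()):  # chain: this link is second
                for rr, y in links_in.get(a, set()).copy():
                    if rr == r1:
                        add_link(s, y, b)

    unsat = {x for x, subs in S.items() if BOT in subs and x != BOT}
    return SubsumptionIndex(subsumers=S, unsatisfiable=unsat)


def classify(ontology: Ontology, extra: list[SubClassOf] | tuple[SubClassOf, ...] = ()) -> SubsumptionIndex:
    """Normalize and saturate in one step."""
    return saturate(normalize(ontology, extra))


# ---------------------------------------------------------------------------
# Expression-level queries
# ---------------------------------------------------------------------------

def _query_gcis(name: str, expr: ClassExpression) -> list[SubClassOf]:
    return [SubClassOf(Named(name), expr), SubClassOf(expr, Named(name))]


def is_subsumed(sub: ClassExpression, sup: ClassExpression, ontology: Ontology) -> bool:
    """Does the ontology entail sub ⊑ sup?  Sound and complete for EL."""
    q1, q2 = f"{QUERY_PREFIX}:sub", f"{QUERY_PREFIX}:sup"
    index = classify(ontology, _query_gcis(q1, sub) + _query_gcis(q2, sup))
    return index.is_subsumed(q1, q2)


def is_satisfiable(expr: ClassExpression, ontology: Ontology) -> bool:
    """Can the expression have instances under the ontology's axioms?"""
    q = f"{QUERY_PREFIX}:sat"
    index = classify(ontology, _query_gcis(q, expr))
    return q not in index.unsatisfiable


def most_specific_classes(expr: ClassExpression, ontology: Ontology) -> set[str]:
    """The minimal named ontology classes subsuming the expression (the MSC).

    Incomparable minima are all returned.  Raises
    :class:`UnsatisfiableExpressionError` for an unsatisfiable expression.
    """
    q = f"{QUERY_PREFIX}:msc"
    index = classify(ontology, _query_gcis(q, expr))
    return msc_from_index(index, q, ontology, expr)


def msc_from_index(
    index: SubsumptionIndex,
    q: str,
    ontology: Ontology,
    expr: ClassExpression | None = None,
) -> set[str]:
    """MSC extraction from a classification that already includes query q ≡ expr."""
    if q in index.unsatisfiable:
        raise UnsatisfiableExpressionError(f"expression is unsatisfiable: {expr!r}")
    markers = {CONTINUANT_CLASS, OCCURRENT_CLASS}
    candidates = {
        s
        for s in index.named_subsumers(q)
        if s in ontology.terms and not ontology.terms[s].obsolete and s not in markers
    }
    minimal = set()
    for x in candidates:
        strictly_below = any(
            y != x and index.is_subsumed(y, x) and not index.is_subsumed(x, y)
            for y in candidates
        )
        if not strictly_below:
            minimal.add(x)
    return minimal


# ---------------------------------------------------------------------------
# Brute-force oracle (tests only)
# ---------------------------------------------------------------------------

def brute_force_subsumption(
    ontology: Ontology,
    queries: dict[str, ClassExpression] | None = None,
    max_classes: int = 20,
) -> SubsumptionIndex:
    """Naive fixpoint closure over unnormalized expressions.

    Derives subsumption pairs between every expression occurring in the
    axioms (plus query expressions) by iterating structural rules until
    nothing changes.  Independent of :func:`saturate`; intended as a test
    oracle for small ontologies only.
    """
    live_terms = [t for t in ontology.terms.values() if not t.obsolete]
    if len(live_terms) > max_classes:
        raise ReasonerError(
            f"brute-force oracle capped at {max_classes} classes, got {len(live_terms)}"
        )
    queries = queries or {}
    gcis, chains = ontology_axioms(ontology)
    for name, expr in queries.items():
        gcis += _query_gcis(name, expr)

    universe: set[ClassExpression] = {Named(t.id) for t in live_terms}
    universe.add(Bottom())

    def collect(e: ClassExpression) -> None:
        universe.add(e)
        if isinstance(e, Intersection):
            for op in e.operands:
                collect(op)
        elif isinstance(e, SomeValuesFrom):
            collect(e.filler)

    for gci in gcis:
        collect(gci.sub)
        collect(gci.sup)
    # seed chain compositions so the chain rule has somewhere to land
    for r1, r2, s in chains:
        for e in list(universe):
            if isinstance(e, SomeValuesFrom) and e.property == r2:
                universe.add(SomeValuesFrom(s, e.filler))

    exprs = list(universe)
    pairs: set[tuple[ClassExpression, ClassExpression]] = set()

    def add(a: ClassExpression, b: ClassExpression) -> bool:
        if (a, b) in pairs:
            return False
        pairs.add((a, b))
        return True

    bot = Bottom()
    for e in exprs:
        add(e, e)
        add(bot, e)
        if isinstance(e, Intersection):
            for op in e.operands:
                add(e, op)
    for gci in gcis:
        add(gci.sub, gci.sup)

    changed = True
    while changed:
        changed = False
        snapshot = list(pairs)
        # transitivity
        by_sub: dict[ClassExpression, list[ClassExpression]] = {}
        for a, b in snapshot:
            by_sub.setdefault(a, []).append(b)
        for a, b in snapshot:
            for c in by_sub.get(b, ()):
                changed |= add(a, c)
        # X ⊑ every operand  =>  X ⊑ the intersection
        for e in exprs:
            if isinstance(e, Intersection):
                for x in exprs:
                    if all((x, op) in pairs for op in e.operands):
                        changed |= add(x, e)
        # monotonicity of existentials: A ⊑ B  =>  ∃r.A ⊑ ∃r.B
        for e1 in exprs:
            if not isinstance(e1, SomeValuesFrom):
                continue
            for e2 in exprs:
                if (
                    isinstance(e2, SomeValuesFrom)
                    and e1.property == e2.property
                    and (e1.filler, e2.filler) in pairs
                ):
                    changed |= add(e1, e2)
            # bottom filler: ∃r.⊥ has no instances
            if (e1.filler, bot) in pairs:
                changed |= add(e1, bot)
        # binary chains: X ⊑ ∃r1.Y, Y ⊑ ∃r2.Z  =>  X ⊑ ∃s.Z
        for r1, r2, s in chains:
            for x, e1 in snapshot:
                if not (isinstance(e1, SomeValuesFrom) and e1.property == r1):
                    continue
                y = e1.filler
                for yy, e2 in snapshot:
                    if yy != y or not (isinstance(e2, SomeValuesFrom) and e2.property == r2):
                        continue
                    target = SomeValuesFrom(s, e2.filler)
                    if target in universe:
                        changed |= add(x, target)

    named = {e: e.id for e in exprs if isinstance(e, Named)}
    subsumers: dict[str, set[str]] = {}
    for e, name in named.items():
        subs = {named[f] for f in exprs if isinstance(f, Named) and (e, f) in pairs}
        if (e, bot) in pairs:
            subs.add(BOT)
        subsumers[name] = subs
    unsat = {n for n, subs in subsumers.items() if BOT in subs}
    # an unsatisfiable class is subsumed by everything
    for n in unsat:
        subsumers[n] = set(subsumers) | {BOT}
    return SubsumptionIndex(subsumers=subsumers, unsatisfiable=unsat)
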