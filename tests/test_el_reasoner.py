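"""EL completion reasoner: normalization, saturation, queries, oracle agreement."""

import random

import pytest

from goext import el_reasoner as el
from goext.el_reasoner import (
    BOT,
    NormalizedAxiomSet,
    ReasonerError,
    SubClassOf,
    UnsatisfiableExpressionError,
    brute_force_subsumption,
    classify,
    is_satisfiable,
    is_subsumed,
    most_specific_classes,
    normalize,
    saturate,
)
from goext.fixtures import random_ontology
from goext.ontology_model import Ontology, OntologyTerm, RelationDef
from goext.owl_mapping import Intersection, Named, SomeValuesFrom


def mini(terms, **axioms):
    onto = Ontology()
    for t in terms:
        onto.add_term(OntologyTerm(id=t, label=t, aspect=axioms.get("aspects", {}).get(t, "external")))
    onto.subclass_axioms = axioms.get("is_a", [])
    onto.relationship_axioms = axioms.get("rels", [])
    onto.equivalence_axioms = axioms.get("equiv", [])
    onto.disjointness_axioms = axioms.get("disjoint", [])
    return onto


class TestNormalize:
    def test_atomic_axiom_passes_through(self):
        onto = mini(["A:1", "A:2"], is_a=[("A:1", "A:2")])
        nas = normalize(onto)
        assert ("A:1", "A:2") in nas.atomic_subsumptions

    def test_intersection_definition_yields_fresh_name(self):
        expr = Intersection(
            (Named("GO:0005635"), SomeValuesFrom("BFO:0000050", Named("CL:0002495")))
        )
        nas = normalize(None, el._query_gcis("__q:0", expr))
        fresh = {a for a in nas.atoms() if a.startswith(el.FRESH_PREFIX)}
        # one fresh name for the existential used on the conjunction's left side
        assert len(fresh) == 1
        assert any(b == "__q:0" for _, _, b in nas.conjunctions)
        assert ("__q:0", "GO:0005635") in nas.atomic_subsumptions
        assert ("__q:0", "BFO:0000050", "CL:0002495") in nas.existential_right

    def test_deterministic_fresh_names(self):
        onto = mini(["A:1", "A:2", "A:3"],
                    rels=[("A:1", "r", "A:2"), ("A:2", "r", "A:3")])
        assert normalize(onto) == normalize(onto)


class TestSaturate:
    def test_empty_axiom_set_gives_reflexive_only(self):
        index = saturate(NormalizedAxiomSet())
        assert index.subsumers == {}
        assert not index.unsatisfiable

    def test_transitive_closure(self):
        onto = mini(["A:1", "A:2", "A:3"], is_a=[("A:1", "A:2"), ("A:2", "A:3")])
        index = classify(onto)
        assert index.is_subsumed("A:1", "A:3")
        assert not index.is_subsumed("A:3", "A:1")

    def test_range_violation_is_unsatisfiable(self, ontology):
        # occurs_in ranges over continuants; apoptosis is a process
        expr = Intersection(
            (Named("GO:0004601"), SomeValuesFrom("BFO:0000066", Named("GO:0006915")))
        )
        assert not is_satisfiable(expr, ontology)

    def test_continuant_filler_is_satisfiable(self, ontology):
        expr = Intersection(
            (Named("GO:0004601"), SomeValuesFrom("BFO:0000066", Named("CL:0000540")))
        )
        assert is_satisfiable(expr, ontology)

    def test_disjointness_propagates_to_common_subclass(self):
        onto = mini(["A:1", "A:2", "A:3"],
                    is_a=[("A:3", "A:1"), ("A:3", "A:2")],
                    disjoint=[("A:1", "A:2")])
        index = classify(onto)
        assert index.unsatisfiable == {"A:3"}

    def test_saturation_deterministic(self):
        onto = mini(["A:1", "A:2", "A:3"],
                    is_a=[("A:1", "A:2")], rels=[("A:2", "r", "A:3")])
        nas = normalize(onto)
        assert saturate(nas) == saturate(nas)

    def test_saturation_idempotent(self):
        # feeding derived subsumptions back as axioms derives nothing new
        rng = random.Random(99)
        onto = random_ontology(rng, 10)
        nas = normalize(onto)
        index = saturate(nas)
        for cls, subs in index.subsumers.items():
            for sup in subs:
                if sup != cls:
                    nas.atomic_subsumptions.append((cls, sup))
        again = saturate(nas)
        assert again.subsumers == index.subsumers
        assert again.unsatisfiable == index.unsatisfiable

    def test_cyclic_is_a_collapses_to_equivalence(self):
        onto = mini(["A:1", "A:2"], is_a=[("A:1", "A:2"), ("A:2", "A:1")])
        index = classify(onto)
        assert index.is_subsumed("A:1", "A:2") and index.is_subsumed("A:2", "A:1")
        assert not index.unsatisfiable


class TestQueries:
    def test_expression_subsumes_itself(self, ontology):
        expr = Intersection(
            (Named("GO:0005634"), SomeValuesFrom("BFO:0000050", Named("CL:0000312")))
        )
        assert is_subsumed(expr, expr, ontology)

    def test_astrocyte_nucleus_below_glial_cell_nucleus(self, ontology):
        astro = Intersection(
            (Named("GO:0005634"), SomeValuesFrom("BFO:0000050", Named("CL:0000127")))
        )
        glial = Intersection(
            (Named("GO:0005634"), SomeValuesFrom("BFO:0000050", Named("CL:0000243")))
        )
        assert is_subsumed(astro, glial, ontology)
        assert not is_subsumed(glial, astro, ontology)

    def test_named_term_without_disjointness_satisfiable(self, ontology):
        assert is_satisfiable(Named("GO:0005634"), ontology)

    def test_msc_of_deepened_expression(self, ontology):
        expr = Intersection(
            (Named("GO:0014069"), SomeValuesFrom("BFO:0000050", Named("CL:0000127")))
        )
        assert most_specific_classes(expr, ontology) == {"GO:0097483"}

    def test_msc_of_named_class_is_itself(self, ontology):
        assert most_specific_classes(Named("GO:0005635"), ontology) == {"GO:0005635"}

    def test_msc_errors_on_unsatisfiable(self, ontology):
        expr = Intersection(
            (Named("GO:0004601"), SomeValuesFrom("BFO:0000066", Named("GO:0006915")))
        )
        with pytest.raises(UnsatisfiableExpressionError):
            most_specific_classes(expr, ontology)

    def test_chain_entailment(self, ontology):
        # regulates ∘ occurs_in ⊑ regulates_occurs_in
        nested = Intersection(
            (
                Named("GO:0006357"),
                SomeValuesFrom(
                    "RO:0002211", SomeValuesFrom("BFO:0000066", Named("CL:0000740"))
                ),
            )
        )
        flat_broader = Intersection(
            (
                Named("GO:0006357"),
                SomeValuesFrom("GOREL:regulates_occurs_in", Named("CL:0000540")),
            )
        )
        # retinal ganglion cell ⊑ neuron, so the nested form entails the
        # composite relation to the broader cell type
        assert is_subsumed(nested, flat_broader, ontology)


class TestOracleAgreement:
    def test_oracle_caps_input_size(self):
        onto = mini([f"A:{i}" for i in range(25)])
        with pytest.raises(ReasonerError, match="capped"):
            brute_force_subsumption(onto)

    def test_empty_ontology_reflexive_only(self):
        index = brute_force_subsumption(mini(["A:1", "A:2"]))
        assert index.subsumers["A:1"] == {"A:1"}
        assert not index.unsatisfiable

    @pytest.mark.parametrize("seed", range(100))
    def test_agreement_on_random_ontologies(self, seed):
        rng = random.Random(seed)
        onto = random_ontology(rng, rng.randint(4, 15))
        index = classify(onto)
        oracle = brute_force_subsumption(onto)
        names = list(onto.terms)
        for a in names:
            for b in names:
                assert index.is_subsumed(a, b) == oracle.is_subsumed(a, b), (a, b)
        assert index.unsatisfiable & set(names) == oracle.unsatisfiable

    @pytest.mark.parametrize("seed", range(30))
    def test_query_agreement_on_random_expressions(self, seed):
        rng = random.Random(1000 + seed)
        onto = random_ontology(rng, 10)
        names = sorted(onto.terms)
        expr = Intersection(
            (
                Named(rng.choice(names)),
                SomeValuesFrom("GOREL:r1", Named(rng.choice(names))),
            )
        )
        q = f"{el.QUERY_PREFIX}:x"
        index = classify(onto, el._query_gcis(q, expr))
        oracle = brute_force_subsumption(onto, queries={q: expr})
        for b in names:
            assert index.is_subsumed(q, b) == oracle.is_subsumed(q, b), b
        assert (q in index.unsatisfiable) == (q in oracle.unsatisfiable)

    @pytest.mark.parametrize("seed", range(20))
    def test_monotonicity_adding_axioms_preserves_subsumptions(self, seed):
        rng = random.Random(2000 + seed)
        onto = random_ontology(rng, 10)
        index = classify(onto)
        extra = onto.copy()
        names = sorted(extra.terms)
        extra.subclass_axioms.append((rng.choice(names), rng.choice(names)))
        bigger = classify(extra)
        for cls, subs in index.subsumers.items():
            if cls in bigger.unsatisfiable:
                continue  # unsatisfiable classes subsume everything trivially
            assert subs <= bigger.subsumers.get(cls, set()) | {cls}


def test_index_tsv_dump_lists_nontrivial_pairs():
    onto = mini(["A:1", "A:2"], is_a=[("A:1", "A:2")])
    tsv = classify(onto).to_tsv()
    assert "A:1\tA:2" in tsv
    assert "A:2\tA:1" not in tsv
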