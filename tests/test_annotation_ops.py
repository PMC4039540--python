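"""Folding, unfolding, validation and deepening over annotation corpora."""

from collections import Counter

import pytest

from goext import annotation_ops as ops
from goext import el_reasoner as el
from goext.annotation_ops import UnsatisfiableExpressionError, deepen, fold, unfold, validate
from goext.extension_syntax import (
    AnnotationRecord,
    parse_extension_field,
    read_gaf,
    split_disjunction,
)
from goext.fixtures import generate_fixtures
from goext.owl_mapping import conjunction_to_class_expression


def record(go_term, ext="", aspect="C", qualifier="", oid="X1"):
    return AnnotationRecord(
        db="DB", object_id=oid, go_term=go_term, aspect=aspect, qualifier=qualifier,
        extension=parse_extension_field(ext),
    )


def corpus_key(records):
    """Multiset of (gene product, term, extension-as-set) over split records."""
    out = []
    for r in records:
        for s in split_disjunction(r):
            ext = (
                frozenset(s.extension.conjunctions[0].as_pairs())
                if s.extension.is_extended
                else None
            )
            out.append((s.gene_product_id, s.go_term, ext))
    return Counter(out)


class TestFold:
    def test_makap_folds_under_nuclear_envelope(self, ontology):
        rec = record("GO:0005635", "part_of(CL:0002495),part_of(UBERON:0002082)")
        result = fold([rec], ontology)
        (folded_id,) = result.mapping
        assert result.records[0].go_term == folded_id
        assert not result.records[0].extension.is_extended
        # the application ontology classifies the folded term under its genus
        assert (folded_id, "GO:0005635") in result.application_ontology.subclass_axioms

    def test_no_extensions_means_no_folded_terms(self, ontology):
        recs = [record("GO:0005634"), record("GO:0005635")]
        result = fold(recs, ontology)
        assert result.mapping == {}
        assert result.records == recs

    def test_identical_extensions_share_one_folded_term(self, ontology):
        # same (term, expression-as-set) pair, different conjunct order
        a = record("GO:0005635", "part_of(CL:0002495),part_of(UBERON:0002082)", oid="X1")
        b = record("GO:0005635", "part_of(UBERON:0002082),part_of(CL:0002495)", oid="X2")
        result = fold([a, b], ontology)
        assert len(result.mapping) == 1
        assert result.records[0].go_term == result.records[1].go_term

    def test_disjunctions_split_before_folding(self, ontology):
        rec = record("GO:0008020", "occurs_in(CL:0000740)|occurs_in(CL:0000540)", aspect="F")
        result = fold([rec], ontology)
        assert result.disjunctions_split == 1
        assert len(result.records) == 2
        assert len(result.mapping) == 2

    def test_folded_term_ids_are_content_addressed(self, ontology):
        rec = record("GO:0005635", "part_of(CL:0002495)")
        first = fold([rec], ontology)
        second = fold([rec], ontology)
        assert set(first.mapping) == set(second.mapping)

    def test_unknown_relation_passes_through_with_error(self, ontology):
        rec = record("GO:0005635", "part_of(CL:0002495)")
        bad = record("GO:0005634", "mystery(CL:0000312)", oid="X2")
        result = fold([rec, bad], ontology)
        assert len(result.mapping) == 1
        assert result.records[1] == bad
        assert any(e.rule == "UNKNOWN_RELATION" for e in result.report.entries)

    def test_not_qualified_record_excluded(self, ontology):
        rec = record("GO:0005635", "part_of(CL:0002495)", qualifier="NOT")
        result = fold([rec], ontology)
        assert result.mapping == {}
        assert result.records == [rec]

    def test_unsatisfiable_folded_term_flagged_and_retained(self, ontology):
        rec = record("GO:0004601", "occurs_in(GO:0006915)", aspect="F")
        result = fold([rec], ontology)
        (folded_id,) = result.mapping
        assert folded_id in result.unsatisfiable
        assert folded_id in result.application_ontology.terms
        assert any(e.rule == "UNSATISFIABLE" for e in result.report.entries)

    def test_fold_preserves_corpus_cardinality(self, corpus, ontology):
        result = fold(corpus.records, ontology)
        expected = sum(len(split_disjunction(r)) for r in corpus.records)
        assert len(result.records) == expected
        distinct_pairs = {
            (s.go_term, frozenset(s.extension.conjunctions[0].as_pairs()))
            for r in corpus.records
            for s in split_disjunction(r)
            if s.extension.is_extended and not s.is_negated
        }
        assert len(result.mapping) <= len(distinct_pairs)

    def test_folded_records_terms_exist_in_application_ontology(self, corpus, ontology):
        result = fold(corpus.records, ontology)
        for r in result.records:
            assert r.go_term in result.application_ontology.terms


class TestUnfold:
    def test_defined_term_unfolds_to_genus_plus_extension(self, ontology):
        rec = record("GO:0097483")
        out, report = unfold([rec], ontology)
        assert out[0].go_term == "GO:0014069"
        assert str(out[0].extension) == "part_of(CL:0000243)"
        assert not report.entries

    def test_primitive_term_unchanged(self, ontology):
        rec = record("GO:0005634")
        out, _ = unfold([rec], ontology)
        assert out == [rec]

    def test_existing_extension_merged_conjunctively(self, ontology):
        rec = record("GO:0097483", "exists_during(GO:0007165)")
        out, _ = unfold([rec], ontology)
        assert str(out[0].extension) == "exists_during(GO:0007165),part_of(CL:0000243)"
        assert out[0].go_term == "GO:0014069"

    @pytest.mark.parametrize("seed", range(100))
    def test_fold_unfold_round_trip_on_random_corpora(self, seed):
        bundle = generate_fixtures(seed=seed, size="small")
        onto = bundle.ontology
        records = bundle.corpus_records().records
        folded = fold(records, onto)
        unfolded, _ = unfold(folded.records, folded.application_ontology)
        assert corpus_key(unfolded) == corpus_key(records)

    def test_recursive_unfold_reaches_fixed_point(self, ontology):
        # fold twice through a defined term, then unfold recursively
        rec = record("GO:0014069", "part_of(CL:0000243)")
        folded = fold([rec], ontology)
        out, _ = unfold(folded.records, folded.application_ontology, recursive=True)
        assert out[0].go_term == "GO:0014069"
        assert str(out[0].extension) == "part_of(CL:0000243)"


class TestValidate:
    def test_clean_corpus_has_empty_report(self, corpus, ontology, bundle):
        report = validate(corpus.records, ontology, registry=bundle.registry)
        assert report.entries == []

    def test_occurs_in_process_flagged_unsatisfiable(self, ontology, bundle):
        rec = record("GO:0004601", "occurs_in(GO:0006915)", aspect="F")
        report = validate([rec], ontology, registry=bundle.registry)
        assert [e.rule for e in report.errors] == ["UNSATISFIABLE"]

    def test_unregistered_prefix_flagged(self, ontology, bundle):
        rec = record("GO:0004672", "has_direct_input(NOPEDB:123)", aspect="F")
        report = validate([rec], ontology, registry=bundle.registry)
        assert "PREFIX" in [e.rule for e in report.errors]

    def test_unknown_relation_flagged(self, ontology, bundle):
        rec = record("GO:0004672", "frobnicates(CL:0000540)", aspect="F")
        report = validate([rec], ontology, registry=bundle.registry)
        assert "UNKNOWN_RELATION" in [e.rule for e in report.errors]

    def test_aspect_usage_warning(self, ontology, bundle):
        # occurs_in is not for cellular_component primary terms
        rec = record("GO:0005634", "occurs_in(CL:0000312)")
        report = validate([rec], ontology, registry=bundle.registry)
        assert "USAGE_ASPECT" in [e.rule for e in report.warnings]

    def test_filler_usage_warning(self, ontology, bundle):
        # happens_during takes a GO process, not a cell type
        rec = record("GO:0051403", "happens_during(CL:0000540)", aspect="P")
        report = validate([rec], ontology, registry=bundle.registry)
        assert "USAGE_FILLER" in [e.rule for e in report.warnings]

    def test_duplicate_expression_warned_not_errored(self, ontology, bundle):
        rec = record("GO:0005634", "part_of(CL:0000312),part_of(CL:0000312)")
        report = validate([rec], ontology, registry=bundle.registry)
        assert [e.rule for e in report.warnings] == ["DUPLICATE"]
        assert not report.errors

    def test_entries_ordered_by_record_then_rule(self, ontology, bundle):
        recs = [
            record("GO:0004672", "frobnicates(CL:0000540)", aspect="F", oid="X2"),
            record("GO:0004601", "occurs_in(GO:0006915)", aspect="F", oid="X1"),
        ]
        report = validate(recs, ontology, registry=bundle.registry)
        assert [e.rule for e in report.entries] == ["UNKNOWN_RELATION", "UNSATISFIABLE"]

    def test_report_tsv_has_one_line_per_entry(self, ontology, bundle):
        recs = [record("GO:0004601", "occurs_in(GO:0006915)", aspect="F")]
        report = validate(recs, ontology, registry=bundle.registry)
        assert len(report.to_tsv().splitlines()) == len(report.entries) + 1


class TestDeepen:
    def test_astrocyte_psd_deepens_to_glial_psd(self, ontology):
        rec = record("GO:0014069", "part_of(CL:0000127)")
        out = deepen(rec, ontology)
        assert out.go_term == "GO:0097483"

    def test_exact_differentia_drops_consumed_extension(self, ontology):
        # part_of(glial cell) matches the equivalence axiom exactly
        rec = record("GO:0014069", "part_of(CL:0000243)")
        out = deepen(rec, ontology)
        assert out.go_term == "GO:0097483"
        assert not out.extension.is_extended

    def test_strictly_stronger_extension_is_retained(self, ontology):
        # astrocyte is below glial cell, so GO:0097483 does not capture it fully
        rec = record("GO:0014069", "part_of(CL:0000127)")
        out = deepen(rec, ontology)
        assert str(out.extension) == "part_of(CL:0000127)"

    def test_unextended_record_unchanged(self, ontology):
        rec = record("GO:0014069")
        assert deepen(rec, ontology) == rec

    def test_no_more_specific_class_leaves_record(self, ontology):
        rec = record("GO:0005634", "part_of(CL:0000312)")
        assert deepen(rec, ontology) == rec

    def test_unsatisfiable_expression_raises(self, ontology):
        rec = record("GO:0004601", "occurs_in(GO:0006915)", aspect="F")
        with pytest.raises(UnsatisfiableExpressionError):
            deepen(rec, ontology)

    def test_deepening_is_idempotent(self, corpus, ontology):
        for rec in corpus.records:
            try:
                once = deepen(rec, ontology)
            except UnsatisfiableExpressionError:
                continue
            assert deepen(once, ontology) == once

    def test_deepened_term_subsumes_expression_per_oracle(self, ontology):
        rec = record("GO:0014069", "part_of(CL:0000127)")
        out = deepen(rec, ontology)
        expr = conjunction_to_class_expression(
            rec.go_term, rec.extension.conjunctions[0], ontology.relations
        )
        oracle = el.brute_force_subsumption(
            ontology, queries={"__q:chk": expr}, max_classes=100
        )
        assert oracle.is_subsumed("__q:chk", out.go_term)
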