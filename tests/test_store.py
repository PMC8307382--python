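"""Store tests: persistence round-trips, retrieval with fallback, sequences, OWL."""

import itertools

import pytest
import rdflib

from tutorplan.fixtures import RandomKBSpec, generate_random_kb
from tutorplan.model import (
    BUKKind,
    BloomLevel,
    ComprehensionLevel,
    SchemaError,
    Theme,
)
from tutorplan.store import (
    BUKQuery,
    KBIntegrityError,
    export_owl,
    kb_to_dict,
    load_kb,
    next_qa_in_sequence,
    query_buks,
    retrieve_buk_with_fallback,
    save_kb,
    sequence_group,
)

LEVELS = list(ComprehensionLevel)


def brute_force_query(kb, q):
    """Exhaustive-scan oracle for query_buks."""
    hits = []
    for b in kb.buks.values():
        if b.refers_to != q.scope_item or b.kind is not q.kind:
            continue
        if b.bloom is not q.bloom or b.comprehension is not q.comprehension:
            continue
        if q.theme is not Theme.GENERAL and b.theme is not q.theme:
            continue
        hits.append(b)
    return sorted(
        hits,
        key=lambda b: (0, b.sequence_index, b.id) if b.sequence_index is not None else (1, 0, b.id),
    )


class TestRoundTrips:
    @pytest.mark.parametrize("fmt", ["json", "yaml"])
    def test_save_load_round_trip_is_byte_stable(self, af, fmt):
        kb, _, _ = af
        blob = save_kb(kb, format=fmt)
        again = save_kb(load_kb(blob, format=fmt), format=fmt)
        assert blob == again

    @pytest.mark.parametrize("seed", range(10))
    def test_random_kb_round_trips_losslessly(self, seed):
        kb = generate_random_kb(RandomKBSpec(seed=seed))
        loaded = load_kb(save_kb(kb))
        assert kb_to_dict(loaded) == kb_to_dict(kb)  # field-by-field equality

    def test_empty_document_is_a_schema_error(self):
        with pytest.raises(SchemaError):
            load_kb(b"{}")

    def test_parse_error_reported(self):
        with pytest.raises(SchemaError):
            load_kb(b"{not json")

    def test_bad_enum_reports_location(self):
        doc = (
            b'{"concepts": {"x": {"code": {"code": "1", "preferred_name": "x"},'
            b' "category": "bogus"}}, "facts": {}, "profiles": {}, "buks": {}, "patients": {}}'
        )
        with pytest.raises(SchemaError) as err:
            load_kb(doc)
        assert "/concepts/x/category" in str(err.value)

    def test_dangling_reference_is_integrity_error(self):
        doc = (
            b'{"concepts": {}, "facts": {}, "profiles": {}, "patients": {},'
            b' "buks": {"b": {"kind": "content", "refers_to": "ghost", "theme": "general",'
            b' "bloom": "lower", "comprehension": "low",'
            b' "explanation": {"R": {"text": "t"}}}}}'
        )
        with pytest.raises(KBIntegrityError):
            load_kb(doc)

    def test_committed_fixture_snapshots_match_builders(self, af, backpain):
        from pathlib import Path

        data_dir = Path(__file__).parent / "data"
        for (kb, _, _), name in [(af, "af_warfarin"), (backpain, "backpain")]:
            assert save_kb(kb) == (data_dir / f"{name}.kb.json").read_bytes()


class TestQueryBuks:
    def test_diet_restriction_sequence_found_in_order(self, af):
        kb, _, _ = af
        q = BUKQuery(
            "anticoagulant", Theme.DIET_RESTRICTIONS, BloomLevel.HIGHER,
            BUKKind.QA, ComprehensionLevel.HIGH,
        )
        assert [b.id for b in query_buks(kb, q)] == ["af_qa_1", "af_qa_3"]

    def test_query_on_empty_kb_returns_nothing(self):
        from tutorplan.store import KnowledgeBase

        q = BUKQuery("x", Theme.GENERAL, BloomLevel.LOWER, BUKKind.QA, ComprehensionLevel.LOW)
        assert query_buks(KnowledgeBase(), q) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_on_random_kbs(self, seed):
        kb = generate_random_kb(RandomKBSpec(seed=seed, n_buks=30))
        scopes = list(kb.concepts) + list(kb.facts)
        for scope, theme, bloom, kind, level in itertools.product(
            scopes[:6], [Theme.GENERAL, Theme.DOSAGE], BloomLevel, BUKKind, LEVELS
        ):
            q = BUKQuery(scope, theme, bloom, kind, level)
            assert [b.id for b in query_buks(kb, q)] == [b.id for b in brute_force_query(kb, q)]


class TestFallbackRetrieval:
    def _kb_with_single_buk_at(self, level):
        kb, _, _ = __import__("tutorplan.fixtures", fromlist=["build_af_fixture"]).build_af_fixture()
        buk = kb.buks["af_qa_1"]
        del kb.buks["af_qa_3"]
        buk.comprehension = level
        return kb, buk

    @pytest.mark.parametrize("patient_level", LEVELS)
    @pytest.mark.parametrize("buk_level", LEVELS)
    def test_downward_only_scan_over_full_grid(self, patient_level, buk_level):
        """Fallback finds the unit iff its level is at or below the patient's."""
        kb, buk = self._kb_with_single_buk_at(buk_level)
        q = BUKQuery(
            "anticoagulant", Theme.DIET_RESTRICTIONS, BloomLevel.HIGHER, BUKKind.QA, patient_level
        )
        hit = retrieve_buk_with_fallback(kb, q)
        if buk_level.rank <= patient_level.rank:
            assert hit is not None and hit.id == buk.id
        else:
            assert hit is None

    def test_exact_level_needs_no_fallback(self, af):
        kb, _, _ = af
        q = BUKQuery(
            "anticoagulant", Theme.DIET_RESTRICTIONS, BloomLevel.HIGHER,
            BUKKind.QA, ComprehensionLevel.HIGH,
        )
        assert retrieve_buk_with_fallback(kb, q).id == "af_qa_1"

    @pytest.mark.parametrize("seed", range(20))
    def test_never_returns_above_query_level(self, seed):
        kb = generate_random_kb(RandomKBSpec(seed=seed, n_buks=25))
        for scope in list(kb.concepts)[:6]:
            for level in LEVELS:
                q = BUKQuery(scope, Theme.GENERAL, BloomLevel.LOWER, BUKKind.QA, level)
                hit = retrieve_buk_with_fallback(kb, q)
                if hit is not None:
                    assert hit.comprehension.rank <= level.rank


class TestSequences:
    def test_next_after_first_is_alternative(self, af):
        kb, _, _ = af
        assert next_qa_in_sequence(kb, kb.buks["af_qa_1"]).id == "af_qa_3"

    def test_wraps_from_last_to_first(self, af):
        kb, _, _ = af
        assert next_qa_in_sequence(kb, kb.buks["af_qa_3"]).id == "af_qa_1"

    def test_singleton_wraps_to_itself(self, af):
        kb, _, _ = af
        assert next_qa_in_sequence(kb, kb.buks["af_qa_4"]).id == "af_qa_4"

    @pytest.mark.parametrize("seed", range(15))
    def test_iteration_is_a_cyclic_permutation(self, seed):
        kb = generate_random_kb(RandomKBSpec(seed=seed, n_buks=30))
        for b in kb.buks.values():
            if b.kind is not BUKKind.QA:
                continue
            group = sequence_group(kb, b)
            visited, current = [], b
            for _ in range(len(group)):
                current = next_qa_in_sequence(kb, current)
                visited.append(current.id)
            assert visited[-1] == b.id  # back to start after |group| steps
            assert sorted(visited) == sorted(x.id for x in group)  # each exactly once


class TestOWLExport:
    def test_single_concept_kb_has_one_typed_individual(self):
        from tutorplan.model import ConceptCategory, ConceptCode, MedicalConcept
        from tutorplan.store import KnowledgeBase, ONTOLOGY_NS

        kb = KnowledgeBase()
        kb.concepts["x"] = MedicalConcept(
            id="x", code=ConceptCode("SNOMED-CT", "1", "x"), category=ConceptCategory.CONDITION
        )
        g = rdflib.Graph()
        g.parse(data=export_owl(kb), format="turtle")
        cond = rdflib.URIRef(ONTOLOGY_NS + "Condition")
        assert len(list(g.subjects(rdflib.RDF.type, cond))) == 1

    def test_warfarin_may_prevent_stroke_triple_present(self, af):
        kb, _, _ = af
        from tutorplan.store import INDIVIDUAL_NS, ONTOLOGY_NS

        g = rdflib.Graph()
        g.parse(data=export_owl(kb), format="turtle")
        triple = (
            rdflib.URIRef(INDIVIDUAL_NS + "warfarin"),
            rdflib.URIRef(ONTOLOGY_NS + "may_prevent"),
            rdflib.URIRef(INDIVIDUAL_NS + "stroke"),
        )
        assert triple in g

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_individual_counts_match_entity_counts(self, seed):
        """Counted via an independent rdflib parse of the serialized graph."""
        from tutorplan.store import ONTOLOGY_NS

        kb = generate_random_kb(RandomKBSpec(seed=seed))
        g = rdflib.Graph()
        g.parse(data=export_owl(kb), format="turtle")

        def count_instances(*classes):
            return sum(
                len(list(g.subjects(rdflib.RDF.type, rdflib.URIRef(ONTOLOGY_NS + c))))
                for c in classes
            )

        assert count_instances(
            "Condition", "Observation", "Treatment_Option",
            "Medication", "Service", "Nutrition_Order", "Care_Plan",
        ) == len(kb.concepts)
        assert count_instances("Condition_Fact") == len(kb.facts)
        assert count_instances("Content_BUK", "QA_BUK") == len(kb.buks)
        assert count_instances("Patient") == len(kb.patients)

    def test_export_is_deterministic(self, af):
        kb, _, _ = af
        from tutorplan.fixtures import build_af_fixture

        kb2, _, _ = build_af_fixture()
        assert export_owl(kb) == export_owl(kb2)
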