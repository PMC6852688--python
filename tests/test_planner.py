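"""Bundle retrieval and the three-step aggregation into a message plan."""

import random

import pytest

from sctverbal.fixtures import read_manifest
from sctverbal.lexicon import load_lexicon
from sctverbal.planner import DiseaseBundle, aggregate_messages, retrieve_bundle
from sctverbal.search import SearchResult, find_concept
from sctverbal.terminology import TerminologyGraph

LEX = load_lexicon()


def _plan_key(plan):
    return (
        [(e.key, names) for e, names in plan.messages],
        plan.examples,
        plan.other_related,
    )


class TestRetrieveBundle:
    def test_lupus_bundle_shape(self, lupus_graph):
        bundle = retrieve_bundle(lupus_graph, find_concept(lupus_graph, "Lupus"), LEX)
        assert {k: len(v) for k, v in bundle.outgoing.items()} == {
            "is_a": 2,
            "finding_site": 1,
            "pathological_process": 1,
        }
        assert [key for _, key in bundle.children] == ["due_to", "children", "children", "children"]

    def test_children_ordered_by_concept_id(self, lupus_graph):
        bundle = retrieve_bundle(lupus_graph, find_concept(lupus_graph, "Lupus"), LEX)
        child_ids = [cid for cid, key in bundle.children if key == "children"]
        assert child_ids == sorted(child_ids)
        assert [bundle.names[c] for c in child_ids] == [
            "Systemic lupus erythematosus",
            "Drug-induced lupus erythematosus",
            "Neonatal lupus erythematosus",
        ]

    def test_isolated_concept_yields_empty_bundle(self, lupus_graph):
        # the qualifier concept has no outgoing rows and one incoming none
        bundle = retrieve_bundle(
            lupus_graph, SearchResult("263680009", "AI - autoimmune", "synonym"), LEX
        )
        assert bundle.outgoing == {}
        assert [key for _, key in bundle.children] == ["pathological_process"]

    def test_unresolved_search_rejected(self, lupus_graph):
        with pytest.raises(ValueError):
            retrieve_bundle(lupus_graph, SearchResult(None, "x", "not_found"), LEX)

    def test_synthetic_bundle_matches_row_scan(self, coverage_engine, coverage_dir):
        """Bundle contents equal a direct scan of the fixture's relationship rows."""
        graph = coverage_engine.graph
        for cid, _ in read_manifest(coverage_dir):
            bundle = retrieve_bundle(graph, SearchResult(cid, "x", "preferred"), LEX)
            expected = {}
            for rel in graph.outgoing.get(cid, []):
                expected.setdefault(LEX.key_for_type(rel.type_id), set()).add(rel.destination_id)
            assert {k: set(v) for k, v in bundle.outgoing.items()} == expected
            incoming = {r.source_id for r in graph.incoming.get(cid, [])}
            assert {c for c, _ in bundle.children} == incoming


class TestAggregation:
    def test_lupus_plan_order_and_routing(self, lupus_graph):
        bundle = retrieve_bundle(lupus_graph, find_concept(lupus_graph, "Lupus"), LEX)
        plan = aggregate_messages(bundle, LEX)
        assert [e.key for e, _ in plan.messages] == ["is_a", "finding_site", "pathological_process"]
        assert plan.messages[0][1] == ["Autoimmune disease", "Connective tissue disease"]
        assert plan.examples == [
            "Systemic lupus erythematosus",
            "Drug-induced lupus erythematosus",
            "Neonatal lupus erythematosus",
        ]
        assert plan.other_related == ["Discoid lupus erythematosus"]

    def test_empty_bundle_empty_plan(self):
        bundle = DiseaseBundle(concept_id="1", preferred_name="Void", searched_term="Void")
        plan = aggregate_messages(bundle, LEX)
        assert plan.messages == [] and plan.examples == [] and plan.other_related == []

    def test_rank_order_matches_brute_force_sort(self, coverage_engine, coverage_dir):
        """Message ordering equals an independent sort of the same inputs."""
        graph = coverage_engine.graph
        for cid, _ in read_manifest(coverage_dir):
            bundle = retrieve_bundle(graph, SearchResult(cid, "x", "preferred"), LEX)
            plan = aggregate_messages(bundle, LEX, strict_order=True)
            expected = sorted(
                (LEX.by_key[k].rank for k in bundle.outgoing if k != "other"),
            )
            assert [e.rank for e, _ in plan.messages] == expected
            ranks = [e.rank for e, _ in plan.messages]
            assert ranks == sorted(ranks)  # non-decreasing rank invariant

    def test_children_rank_default_vs_strict(self, lupus_graph):
        bundle = retrieve_bundle(lupus_graph, find_concept(lupus_graph, "Lupus"), LEX)
        children_entry = LEX.by_key["children"]
        default_plan = aggregate_messages(bundle, LEX)
        strict_plan = aggregate_messages(bundle, LEX, strict_order=True)
        assert default_plan.effective_rank(children_entry) < LEX.by_key["finding_site"].rank + 1
        assert strict_plan.effective_rank(children_entry) == children_entry.rank

    def test_conservation_within_caps(self, coverage_engine, coverage_dir):
        """Every bundle target lands exactly once in messages/examples/other."""
        graph = coverage_engine.graph
        for cid, _ in read_manifest(coverage_dir):
            bundle = retrieve_bundle(graph, SearchResult(cid, "x", "preferred"), LEX)
            plan = aggregate_messages(bundle, LEX, max_examples=3, max_other_related=10)
            planned = [n for _, names in plan.messages for n in names]
            planned += plan.examples + plan.other_related
            expected = sorted(bundle.names[t] for ts in bundle.outgoing.values() for t in ts)
            expected += sorted(bundle.names[c] for c, _ in bundle.children)
            assert sorted(planned) == sorted(expected)

    def test_row_permutation_does_not_change_plan(self, coverage_engine, coverage_dir):
        graph = coverage_engine.graph
        rng = random.Random(0)
        shuffled = TerminologyGraph(
            concepts=graph.concepts,
            names=graph.names,
            outgoing={k: rng.sample(v, len(v)) for k, v in graph.outgoing.items()},
            incoming={k: rng.sample(v, len(v)) for k, v in graph.incoming.items()},
        )
        for cid, _ in read_manifest(coverage_dir):
            result = SearchResult(cid, "x", "preferred")
            plan_a = aggregate_messages(retrieve_bundle(graph, result, LEX), LEX)
            plan_b = aggregate_messages(retrieve_bundle(shuffled, result, LEX), LEX)
            assert _plan_key(plan_a) == _plan_key(plan_b)

    def test_each_type_contributes_one_message(self, coverage_engine, coverage_dir):
        graph = coverage_engine.graph
        for cid, _ in read_manifest(coverage_dir):
            bundle = retrieve_bundle(graph, SearchResult(cid, "x", "preferred"), LEX)
            plan = aggregate_messages(bundle, LEX)
            keys = [e.key for e, _ in plan.messages]
            assert len(keys) == len(set(keys))
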