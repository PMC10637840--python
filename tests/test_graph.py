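"""Reference-graph construction, component grouping and concept merging."""
import random

import pytest

from oracle_unionfind import union_find_partition
from theranorm import (
    Curie,
    SourceRecord,
    build_reference_graph,
    default_registry,
    find_concept_components,
    merge_component,
    normalize_corpus,
    select_anchor,
)
from theranorm.fixtures import FixtureSpec, all_records, generate_sources
from theranorm.graph import serialize_concepts

REGISTRY = default_registry()


def _rec(curie: str, xrefs=(), **kw) -> SourceRecord:
    return SourceRecord(
        id=Curie.parse(curie),
        xrefs=frozenset(Curie.parse(x) for x in xrefs),
        **kw,
    )


class TestBuildGraph:
    def test_printed_xref_pair(self):
        records = [_rec("rxcui:282388", ["drugbank:DB00619"]), _rec("drugbank:DB00619")]
        graph = build_reference_graph(records)
        assert len(graph.nodes) == 2
        assert graph.edges == {(Curie("rxcui", "282388"), Curie("drugbank", "DB00619"))}
        assert graph.dangling == []

    def test_no_xrefs_gives_no_edges(self):
        graph = build_reference_graph([_rec(f"ncit:C{i}") for i in range(3)])
        assert len(graph.nodes) == 3 and not graph.edges

    def test_dangling_xref_reported_not_edged(self):
        records = [_rec("ncit:C1", ["atc:L01"])]
        graph = build_reference_graph(records)
        assert not graph.edges
        assert graph.dangling == [(Curie("ncit", "C1"), Curie("atc", "L01"))]
        # the unloaded target never becomes a node
        assert graph.nodes == {Curie("ncit", "C1")}


class TestComponents:
    def test_shared_target_joins_groups(self):
        records = [
            _rec("ncit:A", ["rxcui:B"]),
            _rec("rxcui:B"),
            _rec("chembl:C", ["rxcui:B"]),
        ]
        comps = find_concept_components(build_reference_graph(records))
        assert comps == [{Curie("ncit", "A"), Curie("rxcui", "B"), Curie("chembl", "C")}]

    def test_isolated_nodes_are_singletons(self):
        comps = find_concept_components(
            build_reference_graph([_rec(f"ncit:C{i}") for i in range(3)])
        )
        assert sorted(len(c) for c in comps) == [1, 1, 1]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_union_find_oracle_on_random_digraphs(self, seed):
        rng = random.Random(seed)
        nodes = [Curie("wikidata", f"Q{i}") for i in range(50)]
        records = {n: set() for n in nodes}
        for a in nodes:
            for b in nodes:
                if a != b and rng.random() < 0.05:
                    records[a].add(b)
        recs = [SourceRecord(id=n, xrefs=frozenset(t)) for n, t in records.items()]
        graph = build_reference_graph(recs)
        got = find_concept_components(graph)
        want = union_find_partition(nodes, [(a, b) for a in nodes for b in records[a]])
        assert got == want


class TestSelectAnchor:
    @pytest.mark.parametrize(
        "members,expected",
        [
            (["rxcui:282388", "drugbank:DB00619"], "rxcui:282388"),
            (["chembl:C1", "wikidata:Q1"], "chembl:C1"),
            (["ncit:C100"], "ncit:C100"),
            (["ncit:B2", "ncit:A1"], "ncit:A1"),  # within-source tie: smallest code
        ],
    )
    def test_priority_then_code(self, members, expected):
        got = select_anchor([Curie.parse(m) for m in members], REGISTRY)
        assert str(got) == expected


class TestMerge:
    def test_worked_example_merges_under_rxnorm_anchor(self, imatinib_concepts):
        (concept,) = imatinib_concepts
        assert str(concept.concept_id) == "rxcui:282388"
        assert concept.anchor_source == "rxcui"
        assert len(concept.members) == 9
        assert {
            "Gleevec", "Glivec", "Celonib", "Enliven", "Gleevac", "Imalek",
            "Imatib", "Mesylonib", "Mitinab", "Plivatinib", "Shantinib",
            "Temsan", "Veenat",
        } <= concept.trade_names
        assert "STI-571" in concept.aliases
        # member ids never remain as xrefs of the merged record
        assert not (concept.xrefs & concept.members)

    def test_singleton_merge_is_identity(self):
        rec = _rec("ncit:C1", label="foo", aliases=frozenset({"bar"}))
        concept = merge_component([rec], rec.id, REGISTRY)
        assert concept.concept_id == rec.id
        assert concept.members == frozenset({rec.id})
        assert concept.label == "foo" and concept.aliases == frozenset({"bar"})

    def test_alias_casefold_dedup_keeps_first_surface_form(self):
        a = _rec("rxcui:1", ["ncit:C2"], aliases=frozenset({"x"}))
        b = _rec("ncit:C2", aliases=frozenset({"X"}))
        concept = merge_component([a, b], a.id, REGISTRY)
        assert concept.aliases == frozenset({"x"})  # higher-priority surface wins

    def test_label_fallback_follows_priority_and_is_flagged(self):
        a = _rec("rxcui:1", ["ncit:C2"])  # empty anchor label
        b = _rec("ncit:C2", label="named")
        concept = merge_component([a, b], a.id, REGISTRY)
        assert concept.label == "named" and concept.label_fallback


class TestNormalizeCorpus:
    def test_worked_example_is_one_concept(self, imatinib_concepts):
        assert len(imatinib_concepts) == 1

    def test_singletons_stay_separate(self):
        concepts = normalize_corpus([_rec(f"ncit:C{i}") for i in range(5)])
        assert len(concepts) == 5

    def test_recovers_planted_ground_truth(self):
        per_source, truth = generate_sources(FixtureSpec(seed=11, n_concepts=40))
        concepts = normalize_corpus(all_records(per_source))
        got = sorted(sorted(str(m) for m in c.members) for c in concepts)
        want = sorted(sorted(g) for g in truth.partition())
        assert got == want

    def test_partition_and_anchor_invariants(self):
        per_source, _ = generate_sources(
            FixtureSpec(seed=3, n_concepts=30, xref_dropout_p=0.3)
        )
        records = all_records(per_source)
        concepts = normalize_corpus(records)
        members = [m for c in concepts for m in c.members]
        assert len(members) == len(records)
        assert set(members) == {r.id for r in records}
        for c in concepts:
            anchor_rank = REGISTRY.rank(c.anchor_source)
            assert all(REGISTRY.rank(m.namespace) >= anchor_rank for m in c.members)

    def test_permutation_invariance(self, imatinib_corpus):
        baseline = "\n".join(serialize_concepts(normalize_corpus(imatinib_corpus)))
        rng = random.Random(0)
        for _ in range(5):
            shuffled = list(imatinib_corpus)
            rng.shuffle(shuffled)
            assert "\n".join(serialize_concepts(normalize_corpus(shuffled))) == baseline

    def test_edge_deletion_never_merges_groups(self):
        per_source, _ = generate_sources(FixtureSpec(seed=5, n_concepts=25))
        records = all_records(per_source)
        n_full = len(normalize_corpus(records))
        rng = random.Random(5)
        for _ in range(5):
            thinned = [
                SourceRecord(
                    id=r.id,
                    label=r.label,
                    aliases=r.aliases,
                    trade_names=r.trade_names,
                    xrefs=frozenset(x for x in r.xrefs if rng.random() < 0.6),
                )
                for r in records
            ]
            assert len(normalize_corpus(thinned)) >= n_full
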