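"""Combination subgraph construction: BFS oracle, symmetry, leakage exclusion."""

import numpy as np
import pytest

from combokg.kg import KGError
from combokg.subgraph import VIRTUAL, batch_build, build_subgraph, query_treats_triples
from combokg.synth import SynthConfig, generate
from combokg.train import Dataset, pairs_to_triples

from conftest import toy_kg


def brute_force_bfs(kg, sources, exclude, max_hops=2):
    """Shortest hop distances from a virtual node whose neighbors are `sources`."""
    dist = {VIRTUAL: 0}
    frontier = list(sources)
    for s in sources:
        dist[s] = 1
    hop = 1
    while frontier and hop < max_hops:
        nxt = []
        for node in frontier:
            for t, r in kg.out_adjacency.get(node, ()):
                if (node, r, t) in exclude:
                    continue
                if t not in dist:
                    dist[t] = hop + 1
                    nxt.append(t)
        frontier = nxt
        hop += 1
    return dist


def test_toy_subgraph_matches_bfs_oracle(kg_toy):
    sg = build_subgraph(kg_toy, "d1", "d2")
    ia, ib = kg_toy.vocab.index["d1"], kg_toy.vocab.index["d2"]
    expected = brute_force_bfs(kg_toy, [ia, ib], set())
    assert sg.hops == expected
    # 2 drugs + 4 genes + virtual; disease s1 is 3 hops away and excluded
    assert len(sg.hops) == 7
    assert kg_toy.vocab.index["s1"] not in sg.hops


def test_toy_subgraph_edge_count(kg_toy):
    sg = build_subgraph(kg_toy, "d1", "d2")
    # 4 membership + 4 targets edges in both directions = 4 + 8
    assert len(sg.triples) == 12


def test_drug_order_symmetry(kg_toy):
    a = build_subgraph(kg_toy, "d1", "d2", seed=3)
    b = build_subgraph(kg_toy, "d2", "d1", seed=3)
    assert a.hops == b.hops
    assert a.triples == b.triples
    assert (a.drug_a, a.drug_b) == (b.drug_a, b.drug_b)


def test_isolated_drugs_degenerate_subgraph():
    from combokg.kg import EntityVocab, KnowledgeGraph, RelationVocab
    from combokg.subgraph import prepare_kg

    v = EntityVocab()
    v.add("d1", "drug")
    v.add("d2", "drug")
    kg = prepare_kg(KnowledgeGraph(v, RelationVocab(), set()))
    sg = build_subgraph(kg, "d1", "d2")
    assert sorted(sg.hops.values()) == [0, 1, 1]
    assert len(sg.triples) == 4  # 2 membership edges + inverses


def test_same_drug_rejected(kg_toy):
    with pytest.raises(KGError, match="differ"):
        build_subgraph(kg_toy, "d1", "d1")


def test_non_drug_rejected(kg_toy):
    with pytest.raises(KGError, match="not typed drug"):
        build_subgraph(kg_toy, "d1", "g1")


@pytest.fixture(scope="module")
def synth_ds():
    return Dataset.from_synth(SynthConfig(
        n_drug=12, n_gene=60, n_disease=20, n_pathway=5, n_phenotype=8,
        n_combos=10, n_drug_groups=2, seed=42,
        edge_counts={
            "targets": 60, "associated_with": 100, "interacts_with": 120,
            "gene_in_pathway": 40, "disease_in_pathway": 10,
            "disease_has_phenotype": 20, "gene_has_phenotype": 30,
            "comorbid_with": 8,
        },
    ))


def test_exclusion_soundness_on_synthetic(synth_ds):
    kg = synth_ds.aug
    sgs = batch_build(kg, synth_ds.combinations, policy="exclude_query_treats", seed=0)
    for sg in sgs:
        assert not (set(sg.triples) & sg.excluded)
        # none of this combo's treats labels appear
        own = query_treats_triples(kg, kg.vocab.index[sg.combo_id])
        assert not (set(sg.triples) & own)


def test_policy_none_keeps_query_treats(synth_ds):
    kg = synth_ds.aug
    r_treats = kg.relations.index["treats"]
    with_treats = [
        (c, a, b) for c, a, b in synth_ds.combinations
        if any(h == kg.vocab.index[c] and r == r_treats for h, r, _ in kg.triples)
    ]
    sgs = batch_build(kg, with_treats, policy="none", seed=0)
    for sg in sgs:
        vidx = kg.vocab.index[sg.combo_id]
        own = {(h, r, t) for h, r, t in kg.triples if h == vidx and r == r_treats}
        assert own <= set(sg.triples)


def test_hop_labels_are_shortest_distances(synth_ds):
    kg = synth_ds.aug
    sgs = batch_build(kg, synth_ds.combinations[:4], policy="exclude_query_treats", seed=0)
    for sg in sgs:
        expected = brute_force_bfs(
            kg, [sg.drug_a_idx, sg.drug_b_idx], sg.excluded
        )
        if sg.virtual_idx >= 0:
            # hop-1 kg-neighbors of the combination entity join the oracle
            for t, r in kg.out_adjacency.get(sg.virtual_idx, ()):
                if (sg.virtual_idx, r, t) in sg.excluded:
                    continue
                expected.setdefault(t, 1)
                for t2, r2 in kg.out_adjacency.get(t, ()):
                    if (t, r2, t2) not in sg.excluded:
                        expected.setdefault(t2, 2)
            expected[sg.virtual_idx] = 0
            expected.pop(VIRTUAL, None)
        assert sg.hops == expected


def test_batch_determinism(synth_ds):
    kg = synth_ds.aug
    a = batch_build(kg, synth_ds.combinations, seed=7)
    b = batch_build(kg, synth_ds.combinations, seed=7)
    assert [s.triples for s in a] == [s.triples for s in b]
    assert [s.hops for s in a] == [s.hops for s in b]


def test_unknown_policy_rejected(synth_ds):
    with pytest.raises(KGError, match="unknown exclusion policy"):
        batch_build(synth_ds.aug, synth_ds.combinations, policy="bogus")


def test_max_neighbors_caps_expansion(synth_ds):
    kg = synth_ds.aug
    sg_full = build_subgraph(kg, *synth_ds.combinations[0][1:3], seed=0, max_neighbors=500)
    sg_cap = build_subgraph(kg, *synth_ds.combinations[0][1:3], seed=0, max_neighbors=3)
    assert len(sg_cap.hops) <= len(sg_full.hops)
    assert set(sg_cap.triples) <= set(kg.triples) | set(sg_full.triples)


def test_subgraph_triples_subset_of_augmented_kg(synth_ds):
    kg = synth_ds.aug
    train_triples = pairs_to_triples(synth_ds.truth_pairs[:5], kg)
    sgs = batch_build(kg, synth_ds.combinations, known_treats=train_triples, seed=0)
    allowed = set(kg.triples) | train_triples
    r_mem = kg.relations.index["contains_drug"]
    r_mem_inv = kg.relations.index["contains_drug__inv"]
    for sg in sgs:
        for h, r, t in sg.triples:
            if r in (r_mem, r_mem_inv):
                continue
            assert (h, r, t) in allowed
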