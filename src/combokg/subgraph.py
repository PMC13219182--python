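"""Drug-combination-centric subgraphs.

A combination of two drugs is represented by a virtual combination node
connected to each constituent drug through a dedicated ``contains_drug``
relation.  Its subgraph is the induced neighborhood within two hops of the
virtual node over the bidirectionally augmented graph, so "two hops" reaches
the drugs' direct biological context (targets, and — when not excluded —
known indications).

Leakage control: the ``exclude_query_treats`` policy removes all treats
edges incident to the query combination from its own subgraph, so a
combination's embedding can never see its own labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kg import INVERSE_SUFFIX, KGError, KnowledgeGraph, augment_relations
from .synth import CONTAINS_DRUG, TREATS

VIRTUAL = -1  # global id used for virtual nodes absent from the vocabulary

EXCLUSION_POLICIES = ("exclude_query_treats", "none")


@dataclass
class ComboSubgraph:
    combo_id: str
    drug_a: str
    drug_b: str
    drug_a_idx: int
    drug_b_idx: int
    virtual_idx: int                       # kg index of the combo entity, or VIRTUAL
    hops: dict[int, int]                   # node (global idx) -> hop distance
    triples: list[tuple[int, int, int]]    # global indices; head/tail may be VIRTUAL
    excluded: set[tuple[int, int, int]] = field(default_factory=set)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.hops)

    def to_dict(self) -> dict:
        return {
            "combo_id": self.combo_id,
            "members": [self.drug_a, self.drug_b],
            "hops": {str(k): v for k, v in sorted(self.hops.items())},
            "n_triples": len(self.triples),
            "n_excluded": len(self.excluded),
        }


def prepare_kg(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Ensure the membership relation exists, then augment with inverses.

    Call on an unaugmented graph before building subgraphs or encoding.
    """
    if CONTAINS_DRUG not in kg.relations.index:
        kg.relations.add(CONTAINS_DRUG)
    return augment_relations(kg)


def _membership_relations(kg: KnowledgeGraph) -> tuple[int, int]:
    try:
        r = kg.relations.index[CONTAINS_DRUG]
        r_inv = kg.relations.index[CONTAINS_DRUG + INVERSE_SUFFIX]
    except KeyError as e:
        raise KGError(
            "kg lacks the contains_drug relation; run prepare_kg() first"
        ) from e
    return r, r_inv


def build_subgraph(
    kg: KnowledgeGraph,
    drug_a: str,
    drug_b: str,
    known_treats: set[tuple[int, int, int]] | None = None,
    exclude: set[tuple[int, int, int]] | None = None,
    max_neighbors: int = 200,
    seed: int = 0,
    combo_id: str | None = None,
) -> ComboSubgraph:
    """Two-hop neighborhood of the virtual node for (drug_a, drug_b).

    ``kg`` must be augmented (see :func:`prepare_kg`).  ``known_treats`` are
    additional triples (e.g. training labels kept out of the stored graph)
    treated as part of the traversable edge set.  Edges in ``exclude`` are
    neither traversed nor included.  Nodes whose neighbor count exceeds
    ``max_neighbors`` contribute a seeded uniform sample of neighbors.
    The result is symmetric in (drug_a, drug_b).
    """
    if drug_a == drug_b:
        raise KGError("drug_a and drug_b must differ")
    for d in (drug_a, drug_b):
        if d not in kg.vocab:
            raise KGError(f"unknown drug: {d}")
        if kg.vocab.types[kg.vocab.index[d]] != "drug":
            raise KGError(f"entity is not typed drug: {d}")
    if not kg.relations.augmented:
        raise KGError("kg must be augmented before subgraph construction")

    exclude = set(exclude or ())
    r_mem, r_mem_inv = _membership_relations(kg)
    ia, ib = kg.vocab.index[drug_a], kg.vocab.index[drug_b]
    vidx = kg.vocab.index[combo_id] if combo_id and combo_id in kg.vocab else VIRTUAL

    extra_adj: dict[int, list[tuple[int, int]]] = {}
    for h, r, t in known_treats or ():
        extra_adj.setdefault(h, []).append((t, r))
        inv = kg.relations.inverse_of.get(r)
        if inv is not None:
            extra_adj.setdefault(t, []).append((h, inv))

    def neighbors(node: int) -> list[tuple[int, int]]:
        out = list(kg.out_adjacency.get(node, ())) if node >= 0 else []
        out += extra_adj.get(node, [])
        return [(n, r) for n, r in out if (node, r, n) not in exclude]

    membership = [
        (vidx, r_mem, ia), (ia, r_mem_inv, vidx),
        (vidx, r_mem, ib), (ib, r_mem_inv, vidx),
    ]

    hops: dict[int, int] = {vidx: 0, ia: 1, ib: 1}
    virt_nbrs = sorted(set(n for n, _ in neighbors(vidx)) | {ia, ib}) if vidx >= 0 else [ia, ib]
    virt_nbrs = _cap(virt_nbrs, max_neighbors, seed, salt=0)
    for n in virt_nbrs:
        hops.setdefault(n, 1)
    frontier = sorted(n for n, h in hops.items() if h == 1)
    for salt, node in enumerate(frontier, start=1):
        nbrs = sorted({n for n, _ in neighbors(node)})
        nbrs = _cap(nbrs, max_neighbors, seed, salt=salt)
        for n in nbrs:
            hops.setdefault(n, 2)

    node_set = set(hops)
    triples: set[tuple[int, int, int]] = set()
    for trip in membership:
        if trip not in exclude:
            triples.add(trip)
    for node in sorted(node_set):
        for n, r in neighbors(node):
            if n in node_set:
                triples.add((node, r, n))

    da, db = sorted((drug_a, drug_b))
    return ComboSubgraph(
        combo_id=combo_id or f"{da}+{db}",
        drug_a=da, drug_b=db,
        drug_a_idx=kg.vocab.index[da], drug_b_idx=kg.vocab.index[db],
        virtual_idx=vidx, hops=hops, triples=sorted(triples), excluded=exclude,
    )


def _cap(sorted_nodes: list[int], max_neighbors: int, seed: int, salt: int) -> list[int]:
    if len(sorted_nodes) <= max_neighbors:
        return sorted_nodes
    rng = np.random.default_rng((seed * 1000003 + salt) % (2**31))
    keep = rng.choice(len(sorted_nodes), size=max_neighbors, replace=False)
    return [sorted_nodes[i] for i in sorted(keep)]


def query_treats_triples(
    kg: KnowledgeGraph,
    combo_idx: int,
    known_treats: set[tuple[int, int, int]] | None = None,
) -> set[tuple[int, int, int]]:
    """All treats edges (and inverses) incident to one combination."""
    if TREATS not in kg.relations.index:
        return set()
    r = kg.relations.index[TREATS]
    r_inv = kg.relations.inverse_of.get(r)
    out: set[tuple[int, int, int]] = set()
    for h, rr, t in set(kg.triples) | set(known_treats or ()):
        if rr == r and h == combo_idx:
            out.add((h, rr, t))
            if r_inv is not None:
                out.add((t, r_inv, h))
        elif rr == r_inv and t == combo_idx:
            out.add((h, rr, t))
            out.add((t, r, h))
    return out


def batch_build(
    kg: KnowledgeGraph,
    combinations: list[tuple[str, str, str]],
    known_treats: set[tuple[int, int, int]] | None = None,
    policy: str = "exclude_query_treats",
    max_neighbors: int = 200,
    seed: int = 0,
) -> list[ComboSubgraph]:
    """One subgraph per (combo_id, drug_a, drug_b) under a leakage policy."""
    if not combinations:
        raise KGError("combinations must be nonempty")
    if policy not in EXCLUSION_POLICIES:
        raise KGError(f"unknown exclusion policy: {policy!r}")
    out = []
    for i, (cid, da, db) in enumerate(combinations):
        exclude: set[tuple[int, int, int]] = set()
        if policy == "exclude_query_treats":
            vidx = kg.vocab.index.get(cid, VIRTUAL)
            exclude = query_treats_triples(kg, vidx, known_treats)
        out.append(
            build_subgraph(
                kg, da, db,
                known_treats=known_treats, exclude=exclude,
                max_neighbors=max_neighbors,
                seed=(seed * 9176 + i) % (2**31), combo_id=cid,
            )
        )
    return out
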