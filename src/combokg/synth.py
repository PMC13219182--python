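"""Seeded generator of biomedical-style knowledge graphs with planted indications.

The generator emulates the schema of a drug-repurposing knowledge graph:
five biological entity types (drug, gene, disease, pathway, phenotype)
linked by eight relation types, plus combination entities connected to
their constituent drugs and ``treats`` edges to diseases.

Indications are planted mechanistically: a combination (d1, d2) treats a
disease s when the union of the two drugs' target genes hits the disease's
gene module in at least ``k_mech`` genes AND each drug individually hits the
module.  Requiring both drugs to touch the disease module makes the task
genuinely combination-level — no single drug's neighborhood suffices.
Mechanistic indications are kept with probability 1 - eps and ~eps of the
final treats set consists of uniformly random noise indications, so eps is
the expected fraction of non-mechanistic labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kg import EntityVocab, KGError, KnowledgeGraph, RelationVocab

CONTAINS_DRUG = "contains_drug"
TREATS = "treats"

#: the eight biological relations: name -> (head type, tail type)
BIO_RELATIONS = {
    "targets": ("drug", "gene"),
    "associated_with": ("gene", "disease"),
    "interacts_with": ("gene", "gene"),
    "gene_in_pathway": ("gene", "pathway"),
    "disease_in_pathway": ("disease", "pathway"),
    "disease_has_phenotype": ("disease", "phenotype"),
    "gene_has_phenotype": ("gene", "phenotype"),
    "comorbid_with": ("disease", "disease"),
}

DEFAULT_EDGE_COUNTS = {
    "targets": 1200,
    "associated_with": 2250,
    "interacts_with": 7200,
    "gene_in_pathway": 1800,
    "disease_in_pathway": 450,
    "disease_has_phenotype": 600,
    "gene_has_phenotype": 1200,
    "comorbid_with": 300,
}


@dataclass
class SynthConfig:
    """Desk-scale defaults: ~960 biological entities, ~15k biological triples."""

    n_drug: int = 100
    n_gene: int = 600
    n_disease: int = 150
    n_pathway: int = 40
    n_phenotype: int = 80
    n_combos: int = 120
    # combinations pair drugs within therapeutic-class groups, mirroring how
    # clinical combinations cluster by drug class; this keeps the drug-sharing
    # graph fragmented enough that drug-disjoint inductive folds exist
    n_drug_groups: int = 10
    edge_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EDGE_COUNTS))
    k_mech: int = 2
    eps: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, n in (
            ("n_drug", self.n_drug), ("n_gene", self.n_gene),
            ("n_disease", self.n_disease), ("n_pathway", self.n_pathway),
            ("n_phenotype", self.n_phenotype), ("n_combos", self.n_combos),
        ):
            if n < 0:
                raise KGError(f"{name} must be >= 0, got {n}")
        if not 0.0 <= self.eps <= 1.0:
            raise KGError(f"eps must be in [0, 1], got {self.eps}")
        unknown = set(self.edge_counts) - set(BIO_RELATIONS)
        if unknown:
            raise KGError(f"unknown relations in edge_counts: {sorted(unknown)}")


@dataclass
class PlantedTruth:
    """Ground-truth (combination, disease) indications with provenance flags."""

    pairs: list[tuple[str, str, bool]]  # (combo_id, disease_id, is_mechanistic)

    def mechanistic(self) -> set[tuple[str, str]]:
        return {(c, s) for c, s, m in self.pairs if m}

    def all_pairs(self) -> set[tuple[str, str]]:
        return {(c, s) for c, s, _ in self.pairs}


def _type_counts(cfg: SynthConfig) -> dict[str, int]:
    return {
        "drug": cfg.n_drug, "gene": cfg.n_gene, "disease": cfg.n_disease,
        "pathway": cfg.n_pathway, "phenotype": cfg.n_phenotype,
    }


def _sample_pairs(rng, n_head, n_tail, count, symmetric):
    """Uniform sample of `count` distinct pairs; symmetric => unordered, no self."""
    space = n_head * (n_head - 1) // 2 if symmetric else n_head * n_tail
    if count > space:
        raise KGError(f"requested {count} edges but only {space} pairs exist")
    flat = rng.choice(space, size=count, replace=False)
    if symmetric:
        # map flat index to (i, j), i < j, over the upper triangle
        i = (n_head - 2 - np.floor(
            np.sqrt(-8 * flat + 4 * n_head * (n_head - 1) - 7) / 2 - 0.5)).astype(int)
        j = flat + i + 1 - n_head * (n_head - 1) // 2 + (n_head - i) * (n_head - i - 1) // 2
        return np.stack([i, j.astype(int)], axis=1)
    return np.stack([flat // n_tail, flat % n_tail], axis=1)


def mechanistic_pairs(
    drug_targets: dict[int, set[int]],
    disease_genes: dict[int, set[int]],
    combos: list[tuple[int, int]],
    k_mech: int,
) -> list[tuple[int, int]]:
    """Enumerate (combo_index, disease) pairs satisfying the planted rule."""
    out = []
    for ci, (d1, d2) in enumerate(combos):
        t1, t2 = drug_targets[d1], drug_targets[d2]
        union = t1 | t2
        for s, genes in disease_genes.items():
            if len(union & genes) >= k_mech and t1 & genes and t2 & genes:
                out.append((ci, s))
    return out


def generate(cfg: SynthConfig) -> tuple[KnowledgeGraph, list[tuple[str, str, str]], PlantedTruth]:
    """Generate a knowledge graph with planted combination indications.

    Returns the full graph (biological triples + combination membership +
    treats edges), the combination list ``(combo_id, drug_a, drug_b)`` and
    the planted ground truth.  Identical config and seed give bit-identical
    output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    vocab = EntityVocab()
    prefixes = {"drug": "D", "gene": "G", "disease": "S", "pathway": "P", "phenotype": "H"}
    names: dict[str, list[str]] = {}
    for etype, count in _type_counts(cfg).items():
        width = max(3, len(str(max(count - 1, 0))))
        names[etype] = [f"{prefixes[etype]}{i:0{width}d}" for i in range(count)]
        for n in names[etype]:
            vocab.add(n, etype)

    relations = RelationVocab()
    triples: set[tuple[int, int, int]] = set()
    counts = dict(DEFAULT_EDGE_COUNTS)
    counts.update(cfg.edge_counts)
    type_n = _type_counts(cfg)
    for rel, (ht, tt) in BIO_RELATIONS.items():
        count = counts.get(rel, 0)
        if count == 0:
            continue
        symmetric = ht == tt
        pairs = _sample_pairs(rng, type_n[ht], type_n[tt], count, symmetric)
        ridx = relations.add(rel)
        for i, j in pairs:
            triples.add((vocab.index[names[ht][i]], ridx, vocab.index[names[tt][j]]))

    # combinations: distinct unordered drug pairs within drug groups
    if cfg.n_combos > 0:
        groups = max(1, min(cfg.n_drug_groups, cfg.n_drug // 2))
        membership = rng.permutation(cfg.n_drug) % groups
        candidates = [
            (a, b)
            for a in range(cfg.n_drug)
            for b in range(a + 1, cfg.n_drug)
            if membership[a] == membership[b]
        ]
        if cfg.n_combos > len(candidates):
            raise KGError(
                f"requested {cfg.n_combos} combinations but only "
                f"{len(candidates)} intra-group drug pairs exist"
            )
        chosen = rng.choice(len(candidates), size=cfg.n_combos, replace=False)
        pairs = np.array([candidates[i] for i in sorted(chosen)], dtype=int)
    else:
        pairs = np.zeros((0, 2), dtype=int)
    combo_names = [f"C{i:03d}" for i in range(cfg.n_combos)]
    for cn in combo_names:
        vocab.add(cn, "combination")
    combos_local = [(int(a), int(b)) for a, b in pairs]
    combinations = [
        (combo_names[i], names["drug"][a], names["drug"][b])
        for i, (a, b) in enumerate(combos_local)
    ]

    r_contains = relations.add(CONTAINS_DRUG)
    for cn, da, db in combinations:
        triples.add((vocab.index[cn], r_contains, vocab.index[da]))
        triples.add((vocab.index[cn], r_contains, vocab.index[db]))

    # planted indications
    drug_targets: dict[int, set[int]] = {d: set() for d in range(cfg.n_drug)}
    disease_genes: dict[int, set[int]] = {s: set() for s in range(cfg.n_disease)}
    if "targets" in relations.index:
        rt = relations.index["targets"]
        for h, r, t in triples:
            if r == rt:
                drug_targets[h].add(t - cfg.n_drug)
    if "associated_with" in relations.index:
        ra = relations.index["associated_with"]
        gene_base = cfg.n_drug
        dis_base = cfg.n_drug + cfg.n_gene
        for h, r, t in triples:
            if r == ra:
                disease_genes[t - dis_base].add(h - gene_base)

    mech = mechanistic_pairs(drug_targets, disease_genes, combos_local, cfg.k_mech)
    keep = rng.random(len(mech)) >= cfg.eps
    kept = [p for p, k in zip(mech, keep) if k]

    mech_set = set(mech)
    n_noise = int(round(cfg.eps / (1.0 - cfg.eps) * len(kept))) if cfg.eps < 1.0 else 0
    non_mech = [
        (ci, s)
        for ci in range(cfg.n_combos)
        for s in range(cfg.n_disease)
        if (ci, s) not in mech_set
    ]
    noise: list[tuple[int, int]] = []
    if n_noise > 0 and non_mech:
        idx = rng.choice(len(non_mech), size=min(n_noise, len(non_mech)), replace=False)
        noise = [non_mech[i] for i in sorted(idx)]

    r_treats = relations.add(TREATS)
    truth_pairs: list[tuple[str, str, bool]] = []
    for (ci, s), is_mech in [(p, True) for p in kept] + [(p, False) for p in noise]:
        cn, sn = combo_names[ci], names["disease"][s]
        triples.add((vocab.index[cn], r_treats, vocab.index[sn]))
        truth_pairs.append((cn, sn, is_mech))

    kg = KnowledgeGraph(vocab=vocab, relations=relations, triples=triples)
    return kg, combinations, PlantedTruth(pairs=truth_pairs)


def summarize(kg: KnowledgeGraph) -> pd.DataFrame:
    """Per-relation triple counts and per-type entity counts.

    The returned frame has columns (kind, name, count); relation counts sum
    to the total number of triples.
    """
    rel_counts = {name: 0 for name in kg.relations.names}
    for _, r, _ in kg.triples:
        rel_counts[kg.relations.names[r]] += 1
    type_counts = {t: 0 for t in set(kg.vocab.types)}
    for t in kg.vocab.types:
        type_counts[t] += 1
    rows = [("relation", n, c) for n, c in rel_counts.items()]
    rows += [("entity_type", n, c) for n, c in sorted(type_counts.items())]
    return pd.DataFrame(rows, columns=["kind", "name", "count"])


def write_dataset(kg, combinations, truth, out_dir) -> None:
    """Emit triples.tsv / types.tsv / combinations.tsv / truth.tsv."""
    import os

    from .kg import write_triples, write_types

    os.makedirs(out_dir, exist_ok=True)
    write_triples(kg, os.path.join(out_dir, "triples.tsv"))
    write_types(kg, os.path.join(out_dir, "types.tsv"))
    with open(os.path.join(out_dir, "combinations.tsv"), "w", encoding="utf-8") as fh:
        fh.write("# combo_id\tdrug_a\tdrug_b\n")
        for cn, da, db in combinations:
            fh.write(f"{cn}\t{da}\t{db}\n")
    with open(os.path.join(out_dir, "truth.tsv"), "w", encoding="utf-8") as fh:
        fh.write("# combo_id\tdisease\tis_mechanistic\n")
        for cn, sn, m in truth.pairs:
            fh.write(f"{cn}\t{sn}\t{int(m)}\n")


def load_combinations(path) -> list[tuple[str, str, str]]:
    from .kg import _read_tsv_rows

    return [(c, a, b) for _, (c, a, b) in _read_tsv_rows(path, 3)]


def load_truth(path) -> PlantedTruth:
    from .kg import _read_tsv_rows

    return PlantedTruth(
        pairs=[(c, s, bool(int(m))) for _, (c, s, m) in _read_tsv_rows(path, 3)]
    )
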