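"""Heterogeneous knowledge-graph data model and triple I/O.

A knowledge graph is a set of (head, relation, tail) triples over a typed
entity vocabulary.  Entities carry exactly one type out of {drug, gene,
disease, pathway, phenotype, combination}; indices are dense, 0-based and
assigned in first-appearance order so that a fixed input file always yields
the same vocabulary.

Relational-GNN preprocessing (``augment_relations``) adds one inverse
relation per original relation plus a single self-loop relation index.  The
self-loop relation has no materialised triples: the self term of the
message-passing update is handled by the encoder's self weight matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

ENTITY_TYPES = ("drug", "gene", "disease", "pathway", "phenotype", "combination")

ORIGINAL = "original"
INVERSE = "inverse"
SELF_LOOP = "self_loop"

SELF_LOOP_NAME = "__self_loop__"
INVERSE_SUFFIX = "__inv"


class KGError(ValueError):
    """Raised for malformed knowledge-graph inputs or contract violations."""


@dataclass
class EntityVocab:
    """Ordered entity vocabulary: string id -> (dense index, type)."""

    names: list[str] = field(default_factory=list)
    types: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def add(self, name: str, etype: str) -> int:
        if etype not in ENTITY_TYPES:
            raise KGError(f"unknown entity type for {name!r}: {etype!r}")
        if name in self.index:
            if self.types[self.index[name]] != etype:
                raise KGError(f"conflicting types for entity {name!r}")
            return self.index[name]
        idx = len(self.names)
        self.names.append(name)
        self.types.append(etype)
        self.index[name] = idx
        return idx

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def of_type(self, etype: str) -> list[int]:
        return [i for i, t in enumerate(self.types) if t == etype]


@dataclass
class RelationVocab:
    """Ordered relation vocabulary with direction tags.

    Every original relation created before augmentation is tagged
    ``original``; augmentation appends one ``inverse`` partner per original
    plus a single ``self_loop`` index.
    """

    names: list[str] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)
    inverse_of: dict[int, int] = field(default_factory=dict)

    def add(self, name: str, tag: str = ORIGINAL) -> int:
        if name in self.index:
            return self.index[name]
        idx = len(self.names)
        self.names.append(name)
        self.tags.append(tag)
        self.index[name] = idx
        return idx

    def __len__(self) -> int:
        return len(self.names)

    @property
    def augmented(self) -> bool:
        return any(t != ORIGINAL for t in self.tags)

    def originals(self) -> list[int]:
        return [i for i, t in enumerate(self.tags) if t == ORIGINAL]


@dataclass
class KnowledgeGraph:
    """G = (V, E, R): typed entities, relations, deduplicated triples."""

    vocab: EntityVocab
    relations: RelationVocab
    triples: set[tuple[int, int, int]]

    _out_adj: dict[int, list[tuple[int, int]]] | None = None
    _in_adj: dict[int, list[tuple[int, int]]] | None = None

    @property
    def n_entities(self) -> int:
        return len(self.vocab)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def _build_adjacency(self) -> None:
        out: dict[int, list[tuple[int, int]]] = {i: [] for i in range(self.n_entities)}
        inc: dict[int, list[tuple[int, int]]] = {i: [] for i in range(self.n_entities)}
        for h, r, t in sorted(self.triples):
            out[h].append((t, r))
            inc[t].append((h, r))
        self._out_adj, self._in_adj = out, inc

    @property
    def out_adjacency(self) -> dict[int, list[tuple[int, int]]]:
        if self._out_adj is None:
            self._build_adjacency()
        return self._out_adj  # type: ignore[return-value]

    @property
    def in_adjacency(self) -> dict[int, list[tuple[int, int]]]:
        if self._in_adj is None:
            self._build_adjacency()
        return self._in_adj  # type: ignore[return-value]

    def validate(self) -> None:
        nv, nr = self.n_entities, self.n_relations
        for h, r, t in self.triples:
            if not (0 <= h < nv and 0 <= t < nv and 0 <= r < nr):
                raise KGError(f"dangling triple index: ({h}, {r}, {t})")


def _read_tsv_rows(path, n_cols: int) -> Iterable[tuple[int, list[str]]]:
    with io.open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise KGError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated fields, "
                    f"got {len(parts)}"
                )
            yield lineno, parts


def load_types(types_path) -> EntityVocab:
    """Read an ``entity<TAB>type`` map; indices follow file order."""
    vocab = EntityVocab()
    for _, (name, etype) in _read_tsv_rows(types_path, 2):
        vocab.add(name, etype)
    return vocab


def load_triples(triples_path, types_path) -> KnowledgeGraph:
    """Load a deduplicated KnowledgeGraph from triple and type TSV files.

    Entity indices are assigned in first-appearance order over the type map,
    so a fixed pair of input files always produces the same vocabulary.
    Raises :class:`KGError` for malformed lines (with line number) or for
    entities missing from the type map.
    """
    vocab = load_types(types_path)
    relations = RelationVocab()
    triples: set[tuple[int, int, int]] = set()
    for lineno, (h, r, t) in _read_tsv_rows(triples_path, 3):
        for name in (h, t):
            if name not in vocab:
                raise KGError(f"{triples_path}:{lineno}: unknown entity type: {name}")
        triples.add((vocab.index[h], relations.add(r), vocab.index[t]))
    return KnowledgeGraph(vocab=vocab, relations=relations, triples=triples)


def write_triples(kg: KnowledgeGraph, path) -> None:
    """Serialise original-direction triples to TSV (sorted, reproducible)."""
    rel_tags = kg.relations.tags
    with io.open(path, "w", encoding="utf-8") as fh:
        fh.write("# head\trelation\ttail\n")
        for h, r, t in sorted(kg.triples):
            if rel_tags[r] != ORIGINAL:
                continue
            fh.write(f"{kg.vocab.names[h]}\t{kg.relations.names[r]}\t{kg.vocab.names[t]}\n")


def write_types(kg: KnowledgeGraph, path) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        fh.write("# entity\ttype\n")
        for name, etype in zip(kg.vocab.names, kg.vocab.types):
            fh.write(f"{name}\t{etype}\n")


def augment_relations(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Add inverse triples and a self-loop relation index.

    For every (i, r, j) an inverse triple (j, r^-1, i) is added under a new
    ``inverse``-tagged relation; a single ``self_loop`` relation index is
    appended without materialised triples.  Calling twice is an error.
    """
    if kg.relations.augmented:
        raise KGError("already augmented")
    relations = RelationVocab(
        names=list(kg.relations.names),
        tags=list(kg.relations.tags),
        index=dict(kg.relations.index),
    )
    inv_idx: dict[int, int] = {}
    for r in kg.relations.originals():
        inv = relations.add(kg.relations.names[r] + INVERSE_SUFFIX, INVERSE)
        inv_idx[r] = inv
        relations.inverse_of[r] = inv
        relations.inverse_of[inv] = r
    relations.add(SELF_LOOP_NAME, SELF_LOOP)
    triples = set(kg.triples)
    triples.update((t, inv_idx[r], h) for h, r, t in kg.triples)
    return KnowledgeGraph(vocab=kg.vocab, relations=relations, triples=triples)
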