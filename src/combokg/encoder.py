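"""Relational GNN encoder over the biological knowledge graph.

Composition-based message passing in the style of CompGCN: a message from
neighbor j through relation r is psi(h_j, h_r) — subtraction, elementwise
product, or circular correlation — transformed by a direction-specific
weight matrix (original / inverse / self-loop) and aggregated over the
neighborhood.  Relation embeddings are projected each layer by a shared
W_rel.  The update for entity i is

    h_i <- f( agg_{(j,r) in N(i)} W_dir(r) psi(h_j, h_r) + W_self h_i )

with ``agg`` either a plain sum or a degree-normalised mean (default mean,
for scale stability on hub nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .kg import INVERSE, KGError, KnowledgeGraph, ORIGINAL

COMPOSITIONS = ("subtract", "multiply", "circular_correlation")


@dataclass
class EmbeddingState:
    """Per-layer entity and relation embeddings (|V| x kappa, |R| x kappa)."""

    entity_emb: np.ndarray
    relation_emb: np.ndarray
    layer: int = 0

    def copy(self) -> "EmbeddingState":
        return EmbeddingState(self.entity_emb.copy(), self.relation_emb.copy(), self.layer)


@dataclass
class FoundationLayerParams:
    """Weights of one relational convolution layer."""

    W_orig: np.ndarray
    W_inv: np.ndarray
    W_self: np.ndarray
    W_rel: np.ndarray
    psi: str = "multiply"
    activation: str = "tanh"
    dropout: float = 0.1
    aggregation: str = "mean"

    @classmethod
    def init(cls, kappa: int, rng: np.random.Generator, **kw) -> "FoundationLayerParams":
        return cls(
            W_orig=ad.xavier_normal(rng, (kappa, kappa)),
            W_inv=ad.xavier_normal(rng, (kappa, kappa)),
            W_self=ad.xavier_normal(rng, (kappa, kappa)),
            W_rel=ad.xavier_normal(rng, (kappa, kappa)),
            **kw,
        )


def init_state(kg: KnowledgeGraph, kappa: int, seed: int = 0) -> EmbeddingState:
    """Xavier-normal initial embeddings (variance 2/(fan_in+fan_out), fan=kappa)."""
    if kappa <= 0:
        raise KGError(f"kappa must be >= 1, got {kappa}")
    rng = np.random.default_rng(seed)
    return EmbeddingState(
        entity_emb=ad.xavier_normal(rng, (kg.n_entities, kappa)),
        relation_emb=ad.xavier_normal(rng, (kg.n_relations, kappa)),
        layer=0,
    )


def compose(h_j: np.ndarray, h_r: np.ndarray, psi: str) -> np.ndarray:
    """Composition operator on equal-length vectors (or row-aligned matrices)."""
    h_j, h_r = np.asarray(h_j, float), np.asarray(h_r, float)
    if h_j.shape != h_r.shape:
        raise KGError(f"shape mismatch: {h_j.shape} vs {h_r.shape}")
    if psi == "subtract":
        return h_j - h_r
    if psi == "multiply":
        return h_j * h_r
    if psi == "circular_correlation":
        k = h_j.shape[-1]
        return np.fft.irfft(
            np.conj(np.fft.rfft(h_j, axis=-1)) * np.fft.rfft(h_r, axis=-1), n=k, axis=-1
        )
    raise KGError(f"unknown composition operator: {psi!r}")


def compose_t(h_j: Tensor, h_r: Tensor, psi: str) -> Tensor:
    if psi == "subtract":
        return ad.sub(h_j, h_r)
    if psi == "multiply":
        return ad.mul(h_j, h_r)
    if psi == "circular_correlation":
        return ad.ccorr(h_j, h_r)
    raise KGError(f"unknown composition operator: {psi!r}")


class GraphTensors:
    """Precomputed sparse gather/aggregate structure of an augmented graph.

    For each edge direction d in {original, inverse}: a row-gather matrix
    for tail embeddings, one for relation embeddings, and the aggregation
    matrix summing (or mean-averaging) messages into head entities.
    """

    def __init__(self, kg: KnowledgeGraph, aggregation: str = "mean"):
        if not kg.relations.augmented:
            raise KGError("graph must be augmented before encoding")
        if aggregation not in ("mean", "sum"):
            raise KGError(f"unknown aggregation: {aggregation!r}")
        self.n_entities = kg.n_entities
        self.n_relations = kg.n_relations
        trips = sorted(kg.triples)
        heads = np.array([t[0] for t in trips], dtype=np.int64).reshape(-1)
        rels = np.array([t[1] for t in trips], dtype=np.int64).reshape(-1)
        tails = np.array([t[2] for t in trips], dtype=np.int64).reshape(-1)
        deg = np.bincount(heads, minlength=kg.n_entities).astype(float)
        tags = np.array([kg.relations.tags[r] for r in rels]) if len(rels) else np.array([])
        self.dirs: dict[str, dict] = {}
        for dname, tag in (("original", ORIGINAL), ("inverse", INVERSE)):
            mask = tags == tag if len(rels) else np.zeros(0, bool)
            if not mask.any():
                continue
            h, r, t = heads[mask], rels[mask], tails[mask]
            w = 1.0 / deg[h] if aggregation == "mean" else None
            self.dirs[dname] = {
                "tail_G": ad.rows_onehot(t, kg.n_entities),
                "rel_G": ad.rows_onehot(r, kg.n_relations),
                "agg_A": ad.segment_matrix(h, kg.n_entities, weights=w),
            }


def layer_forward_t(
    struct: GraphTensors,
    H: Tensor,
    R: Tensor,
    params: dict[str, Tensor],
    psi: str,
    activation: str,
    dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """One relational convolution on autodiff tensors."""
    act = ad.ACTIVATIONS[activation]
    agg: Tensor | None = None
    for dname, W_key in (("original", "W_orig"), ("inverse", "W_inv")):
        if dname not in struct.dirs:
            continue
        d = struct.dirs[dname]
        hj = ad.spmm(d["tail_G"], H)
        hr = ad.spmm(d["rel_G"], R)
        m = ad.matmul(compose_t(hj, hr, psi), params[W_key])
        contrib = ad.spmm(d["agg_A"], m)
        agg = contrib if agg is None else ad.add(agg, contrib)
    self_term = ad.matmul(H, params["W_self"])
    pre = self_term if agg is None else ad.add(agg, self_term)
    out = act(pre)
    if training and dropout > 0:
        if rng is None:
            raise KGError("training dropout requires an rng")
        mask = (rng.random(out.data.shape) >= dropout) / (1.0 - dropout)
        out = ad.mul(out, ad.constant(mask))
    R_new = ad.matmul(R, params["W_rel"])
    return out, R_new


def _params_to_tensors(p: FoundationLayerParams) -> dict[str, Tensor]:
    return {
        "W_orig": ad.constant(p.W_orig), "W_inv": ad.constant(p.W_inv),
        "W_self": ad.constant(p.W_self), "W_rel": ad.constant(p.W_rel),
    }


def layer_forward(
    kg: KnowledgeGraph, state: EmbeddingState, params: FoundationLayerParams
) -> EmbeddingState:
    """Pure eval-mode convolution; the input state is not mutated."""
    if not np.all(np.isfinite(state.entity_emb)) or not np.all(np.isfinite(state.relation_emb)):
        raise KGError("non-finite embeddings")
    struct = GraphTensors(kg, aggregation=params.aggregation)
    H, R = ad.constant(state.entity_emb), ad.constant(state.relation_emb)
    H2, R2 = layer_forward_t(
        struct, H, R, _params_to_tensors(params), params.psi, params.activation
    )
    return EmbeddingState(H2.data, R2.data, state.layer + 1)


def encode(
    kg: KnowledgeGraph, state: EmbeddingState, layers: list[FoundationLayerParams]
) -> EmbeddingState:
    """Stack convolution layers sequentially (eval mode)."""
    if not layers:
        raise KGError("at least one layer required")
    kappa = state.entity_emb.shape[1]
    for p in layers:
        if p.W_self.shape != (kappa, kappa):
            raise KGError("layer dimension mismatch")
        state = layer_forward(kg, state, p)
    return state
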