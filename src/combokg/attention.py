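"""Attention message passing over combination-centric subgraphs.

Each node v of a subgraph aggregates composed messages m_{u,r,v} =
psi(h_u, h_r) from its neighbors.  Attention weights are a softmax over all
(u, r) pairs in N(v) of LeakyReLU(w_att . m_{u,r,v}); the update is

    e_v = f( sum alpha_{u,r} m_{u,r,v} )
    h_v <- f( W_lam e_v + W_o h_v )

The virtual combination node has no pretrained embedding; it is initialised
as the mean of the two constituent drugs' foundation embeddings (or zeros),
which keeps the embedding symmetric in the drug pair.  Edges are processed
in canonical sorted order so drug-order invariance holds bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import EmbeddingState, compose, compose_t
from .kg import KGError
from .subgraph import VIRTUAL, ComboSubgraph

VIRTUAL_INITS = ("drug_mean", "zeros")


@dataclass
class AttentionLayerParams:
    w_att: np.ndarray          # (kappa,) attention scoring vector
    W_lam: np.ndarray          # (kappa, kappa)
    W_o: np.ndarray            # (kappa, kappa)
    leaky_slope: float = 0.2
    psi: str = "multiply"
    activation: str = "tanh"
    dropout: float = 0.1

    def __post_init__(self):
        if not 0 < self.leaky_slope < 1:
            raise KGError("leaky_slope must be in (0, 1)")

    @classmethod
    def init(cls, kappa: int, rng: np.random.Generator, **kw) -> "AttentionLayerParams":
        return cls(
            w_att=ad.xavier_normal(rng, (kappa, 1))[:, 0],
            W_lam=ad.xavier_normal(rng, (kappa, kappa)),
            W_o=ad.xavier_normal(rng, (kappa, kappa)),
            **kw,
        )


@dataclass
class ComboEmbedding:
    combo_id: str
    vector: np.ndarray
    provenance: dict | None = None


def attention_weights(messages, params: AttentionLayerParams) -> np.ndarray:
    """Softmax over LeakyReLU(w_att . m) for a list of message vectors."""
    messages = np.atleast_2d(np.asarray(messages, float))
    if messages.size == 0:
        raise KGError("empty message list")
    logits = messages @ params.w_att
    logits = np.where(logits > 0, logits, params.leaky_slope * logits)
    z = np.exp(logits - logits.max())
    return z / z.sum()


class SubgraphBatch:
    """Edge-list view of one or more subgraphs as disjoint local graphs.

    Local node ids concatenate the subgraphs; for each edge (h, r, t) of a
    subgraph a message flows t -> h.  Built once per subgraph set and reused
    every forward pass.
    """

    def __init__(self, subgraphs: list[ComboSubgraph], n_relations: int):
        self.subgraphs = subgraphs
        self.n_relations = n_relations
        node_global: list[int] = []
        self.virtual_rows: list[int] = []
        self.drug_rows: list[tuple[int, int]] = []
        edges: list[tuple[int, int, int]] = []  # (target_local, rel, source_local)
        for sg in subgraphs:
            offset = len(node_global)
            local = {g: offset + i for i, g in enumerate(sg.nodes)}
            node_global.extend(sg.nodes)
            self.virtual_rows.append(local[sg.virtual_idx])
            for h, r, t in sorted(sg.triples):
                edges.append((local[h], r, local[t]))
        self.node_global = np.array(node_global, dtype=np.int64)
        self.n_nodes = len(node_global)
        edges.sort()
        self.targets = np.array([e[0] for e in edges], dtype=np.int64)
        self.rels = np.array([e[1] for e in edges], dtype=np.int64)
        self.sources = np.array([e[2] for e in edges], dtype=np.int64)
        self.src_G = ad.rows_onehot(self.sources, self.n_nodes)
        self.rel_G = ad.rows_onehot(self.rels, n_relations)
        self.agg_A = ad.segment_matrix(self.targets, self.n_nodes)

    def initial_nodes(self, state: EmbeddingState, virtual_init: str = "drug_mean") -> np.ndarray:
        """Gather foundation embeddings; virtual rows get the drug mean (or zeros)."""
        return _initial_nodes(self, state, virtual_init)


def attention_layer_t(
    batch: SubgraphBatch,
    X: Tensor,
    R: Tensor,
    params: dict[str, Tensor],
    psi: str,
    activation: str,
    leaky_slope: float = 0.2,
    dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """One attention layer over all batched subgraph nodes."""
    act = ad.ACTIVATIONS[activation]
    hu = ad.spmm(batch.src_G, X)
    hr = ad.spmm(batch.rel_G, R)
    m = compose_t(hu, hr, psi)                                    # (E, kappa)
    logits = ad.matmul(m, ad.reshape(params["w_att"], (-1, 1)))   # (E, 1)
    logits = ad.leaky_relu(logits, leaky_slope)
    alpha = ad.segment_softmax(logits, batch.targets, batch.n_nodes)
    e = act(ad.spmm(batch.agg_A, ad.mul(alpha, m)))               # (N, kappa)
    out = act(ad.add(ad.matmul(e, params["W_lam"]), ad.matmul(X, params["W_o"])))
    if training and dropout > 0:
        if rng is None:
            raise KGError("training dropout requires an rng")
        mask = (rng.random(out.data.shape) >= dropout) / (1.0 - dropout)
        out = ad.mul(out, ad.constant(mask))
    return out


def _layer_tensors(p: AttentionLayerParams) -> dict[str, Tensor]:
    return {
        "w_att": ad.constant(p.w_att),
        "W_lam": ad.constant(p.W_lam),
        "W_o": ad.constant(p.W_o),
    }


def combo_layer_forward(
    subgraph: ComboSubgraph,
    state: EmbeddingState,
    params: AttentionLayerParams,
    virtual_init: str = "drug_mean",
) -> tuple[EmbeddingState, np.ndarray]:
    """Eval-mode attention update of one subgraph's nodes.

    Returns the updated state (non-subgraph nodes untouched) and the
    virtual node's updated vector.
    """
    batch = SubgraphBatch([subgraph], state.relation_emb.shape[0])
    X = ad.constant(_initial_nodes(batch, state, virtual_init))
    out = attention_layer_t(
        batch, X, ad.constant(state.relation_emb), _layer_tensors(params),
        params.psi, params.activation, params.leaky_slope,
    )
    new = state.copy()
    real = batch.node_global >= 0
    new.entity_emb[batch.node_global[real]] = out.data[real]
    return new, out.data[batch.virtual_rows[0]]


def _initial_nodes(batch: SubgraphBatch, state: EmbeddingState, virtual_init: str) -> np.ndarray:
    if virtual_init not in VIRTUAL_INITS:
        raise KGError(f"unknown virtual_init: {virtual_init!r}")
    emb = state.entity_emb
    X = np.zeros((batch.n_nodes, emb.shape[1]))
    real = batch.node_global >= 0
    if real.any() and (batch.node_global[real] >= emb.shape[0]).any():
        raise KGError("subgraph node missing from embedding state")
    X[real] = emb[batch.node_global[real]]
    for sg, vrow in zip(batch.subgraphs, batch.virtual_rows):
        if virtual_init == "drug_mean":
            X[vrow] = 0.5 * (emb[sg.drug_a_idx] + emb[sg.drug_b_idx])
        else:
            X[vrow] = 0.0
    return X


def embed_combination(
    subgraph: ComboSubgraph,
    foundation_state: EmbeddingState,
    layer_params: list[AttentionLayerParams],
    virtual_init: str = "drug_mean",
) -> ComboEmbedding:
    """Stack attention layers and read out the virtual node (eval mode).

    Applies only learned aggregation functions, so it works unchanged for
    combinations never seen in training (inductive contract).
    """
    if not subgraph.triples:
        raise KGError("empty subgraph")
    if not layer_params:
        raise KGError("at least one attention layer required")
    batch = SubgraphBatch([subgraph], foundation_state.relation_emb.shape[0])
    X = ad.constant(_initial_nodes(batch, foundation_state, virtual_init))
    R = ad.constant(foundation_state.relation_emb)
    for p in layer_params:
        X = attention_layer_t(
            batch, X, R, _layer_tensors(p), p.psi, p.activation, p.leaky_slope
        )
    return ComboEmbedding(
        combo_id=subgraph.combo_id,
        vector=X.data[batch.virtual_rows[0]].copy(),
        provenance={"n_nodes": batch.n_nodes, "n_edges": len(batch.targets)},
    )
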