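"""Foundation encoder: composition ops, dense-matrix oracle, equivariance."""

import numpy as np
import pytest

from combokg.encoder import (
    EmbeddingState,
    FoundationLayerParams,
    compose,
    encode,
    init_state,
    layer_forward,
)
from combokg.kg import (
    EntityVocab,
    KGError,
    KnowledgeGraph,
    RelationVocab,
    augment_relations,
)

from conftest import toy_kg


def small_kg(triples, n_entities, n_relations):
    v = EntityVocab()
    for i in range(n_entities):
        v.add(f"e{i}", "gene")
    r = RelationVocab()
    for i in range(n_relations):
        r.add(f"r{i}")
    return augment_relations(KnowledgeGraph(v, r, set(triples)))


def dense_layer_oracle(kg, H, R, params):
    """Literal per-entity evaluation of the update equation."""
    W = {"original": params.W_orig, "inverse": params.W_inv}
    out = np.zeros_like(H)
    for i in range(kg.n_entities):
        msgs = []
        for h, r, t in sorted(kg.triples):
            if h != i:
                continue
            m = compose(H[t], R[r], params.psi)
            msgs.append(m @ W[kg.relations.tags[r]])
        agg = np.mean(msgs, axis=0) if msgs else np.zeros(H.shape[1])
        if params.aggregation == "sum" and msgs:
            agg = np.sum(msgs, axis=0)
        out[i] = np.tanh(agg + H[i] @ params.W_self) if params.activation == "tanh" \
            else agg + H[i] @ params.W_self
    return out, R @ params.W_rel


def test_init_state_deterministic_and_variance(kg_toy):
    s1 = init_state(kg_toy, 64, seed=5)
    s2 = init_state(kg_toy, 64, seed=5)
    assert np.array_equal(s1.entity_emb, s2.entity_emb)
    assert np.array_equal(s1.relation_emb, s2.relation_emb)
    with pytest.raises(KGError):
        init_state(kg_toy, 0)


def test_compose_identity_cases(rng):
    h = rng.normal(size=8)
    assert np.allclose(compose(h, np.zeros(8), "subtract"), h)
    assert np.allclose(compose(h, np.ones(8), "multiply"), h)
    with pytest.raises(KGError):
        compose(h, np.zeros(4), "subtract")
    with pytest.raises(KGError):
        compose(h, h, "bogus")


def test_circular_correlation_matches_double_loop(rng):
    a, b = rng.normal(size=(2, 3))
    got = compose(a, b, "circular_correlation")
    want = np.array([sum(a[d] * b[(d + k) % 3] for d in range(3)) for k in range(3)])
    assert np.allclose(got, want, atol=1e-12)


@pytest.mark.parametrize("psi", ["subtract", "multiply", "circular_correlation"])
@pytest.mark.parametrize("aggregation", ["mean", "sum"])
def test_layer_forward_matches_dense_oracle(psi, aggregation, rng):
    kg = small_kg({(0, 0, 1), (1, 1, 2), (2, 0, 3), (0, 1, 3), (3, 1, 4)}, 6, 2)
    kappa = 4
    state = init_state(kg, kappa, seed=2)
    params = FoundationLayerParams.init(
        kappa, rng, psi=psi, aggregation=aggregation, activation="tanh"
    )
    out = layer_forward(kg, state, params)
    H_want, R_want = dense_layer_oracle(kg, state.entity_emb, state.relation_emb, params)
    assert np.allclose(out.entity_emb, H_want, atol=1e-10)
    assert np.allclose(out.relation_emb, R_want, atol=1e-10)


def test_two_node_hand_computed_update():
    kg = small_kg({(0, 0, 1)}, 2, 1)
    kappa = 2
    I = np.eye(kappa)
    params = FoundationLayerParams(
        W_orig=I, W_inv=2 * I, W_self=3 * I, W_rel=I,
        psi="subtract", activation="identity", aggregation="sum",
    )
    H = np.array([[1.0, 2.0], [3.0, 4.0]])
    R = np.array([[0.5, 0.5], [0.25, 0.25], [0.0, 0.0]])  # r0, r0_inv, self_loop
    state = EmbeddingState(H, R)
    out = layer_forward(kg, state, params)
    # node 0: (h1 - r0) @ I + h0 @ 3I ; node 1: (h0 - r0_inv) @ 2I + h1 @ 3I
    assert np.allclose(out.entity_emb[0], (H[1] - R[0]) + 3 * H[0])
    assert np.allclose(out.entity_emb[1], 2 * (H[0] - R[1]) + 3 * H[1])


def test_isolated_entity_gets_self_term_only(rng):
    kg = small_kg({(0, 0, 1)}, 3, 1)  # entity 2 isolated
    state = init_state(kg, 4, seed=0)
    params = FoundationLayerParams.init(4, rng)
    out = layer_forward(kg, state, params)
    want = np.tanh(state.entity_emb[2] @ params.W_self)
    assert np.allclose(out.entity_emb[2], want)


def test_permutation_equivariance(rng):
    triples = {(0, 0, 1), (1, 1, 2), (2, 0, 3), (3, 0, 0)}
    kg = small_kg(triples, 4, 2)
    perm = np.array([2, 0, 3, 1])
    kg_p = small_kg({(perm[h], r, perm[t]) for h, r, t in triples}, 4, 2)
    state = init_state(kg, 4, seed=3)
    state_p = EmbeddingState(state.entity_emb[np.argsort(perm)], state.relation_emb)
    params = FoundationLayerParams.init(4, rng)
    out = layer_forward(kg, state, params)
    out_p = layer_forward(kg_p, state_p, params)
    assert np.allclose(out_p.entity_emb[perm], out.entity_emb, atol=1e-12)


def test_encode_stacks_layers(rng):
    kg = small_kg({(0, 0, 1), (1, 1, 2)}, 3, 2)
    state = init_state(kg, 4, seed=1)
    p1 = FoundationLayerParams.init(4, rng)
    p2 = FoundationLayerParams.init(4, rng)
    manual = layer_forward(kg, layer_forward(kg, state, p1), p2)
    stacked = encode(kg, state, [p1, p2])
    assert np.allclose(stacked.entity_emb, manual.entity_emb)
    # single layer is exactly layer_forward
    assert np.allclose(
        encode(kg, state, [p1]).entity_emb, layer_forward(kg, state, p1).entity_emb
    )


def test_zero_weights_annihilate(rng):
    kg = small_kg({(0, 0, 1)}, 2, 1)
    state = init_state(kg, 4, seed=1)
    z = np.zeros((4, 4))
    params = FoundationLayerParams(
        W_orig=z, W_inv=z, W_self=z, W_rel=z, activation="identity"
    )
    out = layer_forward(kg, state, params)
    assert np.all(out.entity_emb == 0)


def test_layer_forward_is_pure(rng):
    kg = small_kg({(0, 0, 1)}, 2, 1)
    state = init_state(kg, 4, seed=1)
    before = state.entity_emb.copy()
    layer_forward(kg, state, FoundationLayerParams.init(4, rng))
    assert np.array_equal(state.entity_emb, before)


def test_non_finite_input_rejected(rng):
    kg = small_kg({(0, 0, 1)}, 2, 1)
    state = init_state(kg, 4, seed=1)
    state.entity_emb[0, 0] = np.nan
    with pytest.raises(KGError, match="non-finite"):
        layer_forward(kg, state, FoundationLayerParams.init(4, rng))
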