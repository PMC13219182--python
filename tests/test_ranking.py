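"""Splits, negative enumeration, filtered ranking, metrics, RotatE scorer."""

import numpy as np
import pytest

from combokg.kg import KGError
from combokg.ranking import (
    SplitSpec,
    aggregate_metrics,
    enumerate_negatives,
    evaluate_scores,
    filtered_rank,
    make_split,
    random_baseline_mrr,
    rotate_score,
)
from combokg.synth import SynthConfig, generate


def brute_rank(scores, pos, mask):
    """Sort-based oracle with mean tie rank, restricted to mask."""
    s = scores[mask]
    pos_s = scores[pos]
    order = np.argsort(-s, kind="stable")
    better = np.sum(s > pos_s)
    tied = np.sum(s == pos_s) - 1
    return 1.0 + better + tied / 2.0


def brute_auroc(scores, labels):
    """Concordant-pair counting with ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ------------------------------------------------------------------- splits

@pytest.fixture(scope="module")
def synth():
    kg, combos, truth = generate(SynthConfig(seed=11))
    return kg, combos, [(c, s) for c, s, _ in truth.pairs]


def test_transductive_sizes_and_disjointness():
    pairs = [(f"C{i:03d}", f"S{i % 10}") for i in range(100)]
    combos = [(f"C{i:03d}", "a", "b") for i in range(100)]
    spl = make_split(pairs, combos, SplitSpec(seed=0))
    assert (len(spl.train), len(spl.valid), len(spl.test)) == (60, 20, 20)
    assert not (set(spl.train) & set(spl.valid))
    assert not (set(spl.train) & set(spl.test))
    assert not (set(spl.valid) & set(spl.test))
    assert set(spl.train) | set(spl.valid) | set(spl.test) == set(pairs)


def test_transductive_test_combos_seen_in_training(synth):
    _, combos, pairs = synth
    spl = make_split(pairs, combos, SplitSpec(seed=3))
    train_combos = {c for c, _ in spl.train}
    assert {c for c, _ in spl.test} <= train_combos
    assert {c for c, _ in spl.valid} <= train_combos


def test_split_determinism_and_seed_sensitivity(synth):
    _, combos, pairs = synth
    a = make_split(pairs, combos, SplitSpec(seed=5))
    b = make_split(pairs, combos, SplitSpec(seed=5))
    assert a.train == b.train and a.test == b.test
    others = [make_split(pairs, combos, SplitSpec(seed=5, fold=f)).test for f in range(1, 5)]
    assert any(t != a.test for t in others)


def test_inductive_split_drug_disjoint_over_folds(synth):
    _, combos, pairs = synth
    drugs_of = {c: {a, b} for c, a, b in combos}
    for fold in range(5):
        spl = make_split(pairs, combos, SplitSpec(mode="inductive", seed=9, fold=fold))
        test_drugs = set().union(*(drugs_of[c] for c, _ in spl.test))
        rest_drugs = set().union(
            *(drugs_of[c] for c, _ in spl.train + spl.valid)
        )
        assert not (test_drugs & rest_drugs)
        assert len(spl.test) > 0


def test_bad_fractions_rejected():
    with pytest.raises(KGError):
        SplitSpec(fractions=(0.5, 0.2, 0.2))


# -------------------------------------------------------------- enumeration

def test_enumerate_negatives_partition():
    diseases = [f"S{i}" for i in range(10)]
    gt = {("C1", "S0"), ("C1", "S3")}
    cands, labels = enumerate_negatives(("C1", "S0"), diseases, gt)
    assert (labels == 1).sum() == 1
    assert (labels == -1).sum() == 1  # S3 filtered
    assert (labels == 0).sum() == 8
    assert cands[int(np.where(labels == 1)[0][0])] == "S0"


def test_enumerate_negatives_only_test_triple_known():
    diseases = [f"S{i}" for i in range(6)]
    _, labels = enumerate_negatives(("C1", "S2"), diseases, {("C1", "S2")})
    assert (labels == 0).sum() == 5
    assert (labels == -1).sum() == 0


def test_enumerate_negatives_brute_force_membership(rng):
    diseases = [f"S{i}" for i in range(30)]
    gt = {("C", f"S{i}") for i in rng.choice(30, 8, replace=False)}
    pos = sorted(gt)[0][1]
    _, labels = enumerate_negatives(("C", pos), diseases, gt)
    for k, v in enumerate(diseases):
        if v == pos:
            assert labels[k] == 1
        elif ("C", v) in gt:
            assert labels[k] == -1
        else:
            assert labels[k] == 0


# ----------------------------------------------------------------- ranking

def test_filtered_rank_hand_example():
    scores = np.array([0.9, 0.8, 0.7, 0.6])
    filt = np.array([True, False, False, False])
    raw, f = filtered_rank(scores, 1, filt)
    assert (raw, f) == (2.0, 1.0)


def test_all_tied_scores_get_mean_rank():
    raw, f = filtered_rank(np.ones(5), 2, np.zeros(5, bool))
    assert raw == f == 3.0


def test_filtered_rank_matches_sort_oracle_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        n = rng.integers(2, 40)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        filt = rng.random(n) < 0.3
        if filt.all():
            filt[0] = False
        pos = int(rng.choice(np.where(~filt)[0]))
        raw, f = filtered_rank(scores, pos, filt)
        assert f <= raw
        assert raw == brute_rank(scores, pos, np.ones(n, bool))
        assert f == brute_rank(scores, pos, ~filt)


def test_positive_flagged_filtered_rejected():
    with pytest.raises(KGError):
        filtered_rank(np.ones(3), 0, np.array([True, False, False]))


# ----------------------------------------------------------------- metrics

def test_aggregate_metrics_closed_form():
    res = aggregate_metrics(np.array([1.0, 2.0, 4.0]))
    assert np.isclose(res.mrr, (1 + 0.5 + 0.25) / 3)
    assert np.isclose(res.mrr, 0.583333, atol=1e-6)
    assert np.isclose(res.hits1, 1 / 3)
    assert np.isclose(res.hits3, 2 / 3)
    assert res.hits10 == 1.0


def test_perfect_ranking_all_metrics_one():
    scores = np.array([5.0, 1.0, 0.0])
    labels = np.array([1, 0, 0])
    res = aggregate_metrics(np.ones(4), np.tile(scores, 4), np.tile(labels, 4))
    assert res.hits1 == res.hits10 == res.mrr == 1.0
    assert res.auroc == 1.0 and res.aupr == 1.0


def test_hits_monotone_and_mrr_bounds(rng):
    ranks = rng.integers(1, 50, size=200).astype(float)
    res = aggregate_metrics(ranks)
    assert res.hits1 <= res.hits3 <= res.hits10
    assert res.mrr >= res.hits1
    assert 0 < res.mrr <= 1


def test_auroc_matches_pairwise_oracle():
    rng = np.random.default_rng(23)
    for _ in range(500):
        n = rng.integers(4, 25)
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = aggregate_metrics(np.array([1.0]), scores, labels)
        assert np.isclose(res.auroc, brute_auroc(scores, labels), atol=1e-12)


def test_single_class_labels_warn():
    with pytest.warns(UserWarning, match="single-class"):
        res = aggregate_metrics(np.array([1.0]), np.array([1.0, 2.0]), np.array([1, 1]))
    assert res.auroc is None


def test_random_scorer_mrr_matches_analytic_null():
    rng = np.random.default_rng(31)
    n_dis = 50
    diseases = [f"S{i}" for i in range(n_dis)]
    pairs = [(f"C{i}", diseases[int(rng.integers(n_dis))]) for i in range(400)]
    gt = set(pairs)
    res = evaluate_scores(
        lambda c: rng.normal(size=n_dis), pairs, diseases, gt
    )
    null = random_baseline_mrr(n_dis)
    assert abs(res.mrr - null) <= 3 * res.se["mrr"]


# ------------------------------------------------------------------ rotate

def test_rotate_identity_rotation_gives_gamma(rng):
    h = rng.normal(size=4) + 1j * rng.normal(size=4)
    assert np.isclose(rotate_score(h, np.ones(4), h, gamma=12.0), 12.0)


def test_rotate_global_phase_invariance(rng):
    h = rng.normal(size=4) + 1j * rng.normal(size=4)
    t = rng.normal(size=4) + 1j * rng.normal(size=4)
    r = np.exp(1j * rng.uniform(0, 2 * np.pi, 4))
    phase = np.exp(1j * 0.7)
    assert np.isclose(
        rotate_score(h, r, t), rotate_score(h * phase, r, t * phase), atol=1e-10
    )


def test_rotate_hand_example_90_degrees():
    h = np.array([1.0 + 0j, 0 + 1j])
    r = np.array([1j, 1j])  # 90-degree rotations
    t = np.array([0 + 1j, -1.0 + 0j])
    # h*r = [1j, -1]; h*r - t = 0
    assert np.isclose(rotate_score(h, r, t, gamma=5.0), 5.0)
    t2 = np.array([0 + 0j, 0 + 0j])
    assert np.isclose(rotate_score(h, r, t2, gamma=5.0), 5.0 - 2.0)


def test_rotate_non_unit_relation_rejected():
    with pytest.raises(KGError):
        rotate_score(np.ones(2), np.array([2.0, 1.0]), np.ones(2))
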