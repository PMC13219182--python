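"""Split construction, filtered ranking and aggregate metrics.

Transductive splits shuffle (combination, disease) label pairs 60/20/20 so
every test combination is also seen in training; inductive splits partition
combinations so that test combinations share no constituent drug with any
training or validation combination (connected components of the
drug-sharing graph, smallest first, until the test quota is met).

Ranking is filtered: for each test triple all candidate diseases are
enumerated, other known-true diseases for the same combination are removed,
and the positive's rank among the remainder is recorded.  Ties receive the
mean of their occupied positions, so a constant scorer earns the random
expectation rather than rank 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .kg import KGError

Pair = tuple[str, str]  # (combo_id, disease_id)


@dataclass
class SplitSpec:
    mode: str = "transductive"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    fold: int = 0
    max_test_fraction: float = 0.35  # inductive: abort if quota overshoots this

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise KGError("split fractions must sum to 1")
        if self.mode not in ("transductive", "inductive"):
            raise KGError(f"unknown split mode: {self.mode!r}")


@dataclass
class Split:
    train: list[Pair]
    valid: list[Pair]
    test: list[Pair]
    mode: str = "transductive"


def make_split(
    treats_pairs: list[Pair],
    combinations: list[tuple[str, str, str]],
    spec: SplitSpec,
) -> Split:
    if not treats_pairs:
        raise KGError("no treats pairs to split")
    rng = np.random.default_rng((spec.seed * 7919 + spec.fold) % (2**31))
    pairs = sorted(treats_pairs)
    if spec.mode == "transductive":
        return _transductive(pairs, rng, spec.fractions)
    return _inductive(pairs, combinations, rng, spec)


def _transductive(pairs: list[Pair], rng, fractions) -> Split:
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    n = len(pairs)
    n_tr, n_va = int(n * fractions[0]), int(n * fractions[1])
    train, valid, test = shuffled[:n_tr], shuffled[n_tr:n_tr + n_va], shuffled[n_tr + n_va:]
    # every held-out combination must appear in training: swap pairs in if needed
    train_combos = {c for c, _ in train}
    counts: dict[str, int] = {}
    for c, _ in train:
        counts[c] = counts.get(c, 0) + 1
    for bucket in (valid, test):
        for i, (c, s) in enumerate(bucket):
            if c in train_combos:
                continue
            donor = next(
                (j for j, (dc, _) in enumerate(train) if counts[dc] >= 2), None
            )
            if donor is None:
                break
            dc, ds = train[donor]
            train[donor], bucket[i] = (c, s), (dc, ds)
            counts[dc] -= 1
            counts[c] = counts.get(c, 0) + 1
            train_combos.add(c)
    return Split(train, valid, test, "transductive")


def _inductive(pairs, combinations, rng, spec: SplitSpec) -> Split:
    import networkx as nx

    drugs_of = {cid: frozenset((a, b)) for cid, a, b in combinations}
    g = nx.Graph()
    g.add_nodes_from(drugs_of)
    by_drug: dict[str, list[str]] = {}
    for cid, (ds) in drugs_of.items():
        for d in ds:
            by_drug.setdefault(d, []).append(cid)
    for cids in by_drug.values():
        for a, b in zip(cids, cids[1:]):
            g.add_edge(a, b)
    comps = sorted(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    n_combos = len(drugs_of)
    quota = int(np.ceil(0.2 * n_combos))
    test_combos: set[str] = set()
    for comp in comps:
        if len(test_combos) >= quota:
            break
        test_combos |= comp
    if len(test_combos) < quota or len(test_combos) > spec.max_test_fraction * n_combos:
        raise KGError(
            "cannot carve a drug-disjoint test partition near 20% of combinations; "
            "the drug-sharing graph is too connected — regenerate or adjust the data"
        )
    test = [p for p in pairs if p[0] in test_combos]
    rest = [p for p in pairs if p[0] not in test_combos]
    order = rng.permutation(len(rest))
    rest = [rest[i] for i in order]
    n_va = int(0.25 * len(rest))
    return Split(rest[n_va:], rest[:n_va], test, "inductive")


def constituent_drugs(combos: set[str], combinations) -> set[str]:
    out: set[str] = set()
    for cid, a, b in combinations:
        if cid in combos:
            out |= {a, b}
    return out


# ----------------------------------------------------------------- ranking

def enumerate_negatives(
    test_pair: Pair,
    all_diseases: list[str],
    ground_truth: set[Pair],
) -> tuple[list[str], np.ndarray]:
    """Candidates and labels for one query.

    Labels: 1 = the positive, 0 = negative, -1 = filtered (other known-true
    disease for the same combination).
    """
    combo, disease = test_pair
    if disease not in all_diseases:
        raise KGError(f"positive disease {disease!r} not in candidate set")
    labels = np.zeros(len(all_diseases), dtype=int)
    for k, v in enumerate(all_diseases):
        if v == disease:
            labels[k] = 1
        elif (combo, v) in ground_truth:
            labels[k] = -1
    return list(all_diseases), labels


def filtered_rank(
    scores: np.ndarray,
    positive_index: int,
    filtered: np.ndarray,
    tie_policy: str = "mean",
) -> tuple[float, float]:
    """(raw_rank, filtered_rank) of the positive, descending by score.

    ``filtered`` is a boolean mask of candidates removed before computing
    the filtered rank.  tie_policy='mean' assigns tied candidates the mean
    of the positions they jointly occupy.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise KGError("empty candidate set")
    filtered = np.asarray(filtered, dtype=bool)
    if filtered[positive_index]:
        raise KGError("the positive candidate must not be flagged filtered")
    if tie_policy != "mean":
        raise KGError(f"unknown tie policy: {tie_policy!r}")
    s_pos = scores[positive_index]

    def rank_among(mask: np.ndarray) -> float:
        better = int(np.sum(scores[mask] > s_pos))
        tied = int(np.sum(scores[mask] == s_pos)) - 1  # excluding the positive
        return 1.0 + better + 0.5 * tied

    all_mask = np.ones_like(filtered)
    return rank_among(all_mask), rank_among(~filtered)


@dataclass
class RankingResult:
    per_query: list[dict] = field(default_factory=list)
    hits1: float = np.nan
    hits3: float = np.nan
    hits10: float = np.nan
    mrr: float = np.nan
    auroc: float | None = None
    aupr: float | None = None
    se: dict[str, float] = field(default_factory=dict)
    n_queries: int = 0
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries, "n_skipped": self.n_skipped,
            "hits1": self.hits1, "hits3": self.hits3, "hits10": self.hits10,
            "mrr": self.mrr, "auroc": self.auroc, "aupr": self.aupr,
            "se": dict(self.se),
        }


def aggregate_metrics(
    ranks: np.ndarray,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    per_query: list[dict] | None = None,
    n_skipped: int = 0,
) -> RankingResult:
    """Hits@{1,3,10}, MRR (with SEs) and pooled AUROC / AUPR.

    ``scores``/``labels`` are the pooled (query, candidate) score-label
    pairs with filtered candidates already removed.
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise KGError("at least one query required")
    rr = 1.0 / ranks
    res = RankingResult(
        per_query=per_query or [],
        hits1=float(np.mean(ranks <= 1)),
        hits3=float(np.mean(ranks <= 3)),
        hits10=float(np.mean(ranks <= 10)),
        mrr=float(np.mean(rr)),
        n_queries=int(ranks.size),
        n_skipped=n_skipped,
    )
    n = ranks.size
    res.se = {
        "mrr": float(np.std(rr, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "hits10": float(np.std(ranks <= 10, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    }
    if scores is not None and labels is not None:
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            warnings.warn("AUROC/AUPR undefined: labels are single-class")
        else:
            res.auroc = float(roc_auc_score(labels, scores))
            res.aupr = float(average_precision_score(labels, scores))
    return res


def random_baseline_mrr(n_candidates: int) -> float:
    """Expected reciprocal rank under uniform random ranking: H_n / n."""
    return float(np.sum(1.0 / np.arange(1, n_candidates + 1)) / n_candidates)


def rotate_score(
    h_head: np.ndarray, h_rel: np.ndarray, h_tail: np.ndarray, gamma: float = 12.0
) -> float:
    """Complex-rotation baseline score: gamma - || h o r - t ||_1 (higher = better)."""
    h_head = np.asarray(h_head, complex)
    h_rel = np.asarray(h_rel, complex)
    h_tail = np.asarray(h_tail, complex)
    if not np.allclose(np.abs(h_rel), 1.0, atol=1e-8):
        raise KGError("relation phases must have unit modulus")
    return float(gamma - np.sum(np.abs(h_head * h_rel - h_tail)))


def evaluate_scores(
    score_fn,
    test_pairs: list[Pair],
    all_diseases: list[str],
    ground_truth: set[Pair],
) -> RankingResult:
    """Run the filtered-ranking protocol for a scoring callable.

    ``score_fn(combo_id) -> np.ndarray`` over ``all_diseases``; queries for
    which it raises KGError are skipped (with a warning) and counted.
    """
    ranks, per_query = [], []
    pooled_scores, pooled_labels = [], []
    n_skipped = 0
    score_cache: dict[str, np.ndarray] = {}
    for combo, disease in test_pairs:
        if combo not in score_cache:
            try:
                score_cache[combo] = np.asarray(score_fn(combo), dtype=float)
            except KGError as e:
                warnings.warn(f"skipping queries for {combo}: {e}")
                score_cache[combo] = None  # type: ignore[assignment]
        scores = score_cache[combo]
        if scores is None:
            n_skipped += 1
            continue
        _, labels = enumerate_negatives((combo, disease), all_diseases, ground_truth)
        pos = int(np.where(labels == 1)[0][0])
        raw, filt = filtered_rank(scores, pos, labels == -1)
        ranks.append(filt)
        per_query.append(
            {"combo": combo, "disease": disease, "raw_rank": raw, "filtered_rank": filt}
        )
        keep = labels >= 0  # filtered candidates are excluded from the pool
        pooled_scores.extend(scores[keep])
        pooled_labels.extend((labels[keep] == 1).astype(int))
    if not ranks:
        raise KGError("all test queries were skipped")
    return aggregate_metrics(
        np.array(ranks),
        np.array(pooled_scores),
        np.array(pooled_labels),
        per_query=per_query,
        n_skipped=n_skipped,
    )
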