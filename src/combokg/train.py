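"""Two-stage training of the dual-layer model and its ablation variants.

Stage 1 (foundation): link prediction over the biological graph.  The
relational encoder is run on the full graph each step; a sampled batch of
(head, relation) queries is scored against every entity with the shared
convolutional decoder under a multi-label 1-vs-all binary cross-entropy
(every known tail of the query is a positive, every other entity a
negative).

Stage 2 (combination): the attention encoder embeds each training
combination from its leakage-filtered subgraph; the decoder scores the
embedding against every disease under the same 1-vs-all objective.
Foundation embeddings are frozen by default; the checkpoint with the best
validation filtered MRR is kept.

Variants: ``dual`` (both stages), ``onelayer`` (combinations and treats
edges merged into a single graph encoded by the foundation encoder alone),
``subgraph_only`` (no pretraining; Xavier-initialised embeddings trained
through the subgraph encoder only).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .attention import SubgraphBatch, attention_layer_t
from .decoder import Decoder, DecoderConfig
from .encoder import EmbeddingState, GraphTensors, layer_forward_t
from .kg import KGError, KnowledgeGraph, INVERSE_SUFFIX
from .ranking import Split, evaluate_scores, RankingResult
from .subgraph import batch_build, build_subgraph, prepare_kg
from .synth import CONTAINS_DRUG, TREATS, SynthConfig, generate

VARIANTS = ("dual", "onelayer", "subgraph_only")


def _pos_weight(targets: np.ndarray, setting) -> float | None:
    if setting in (None, 1.0, "none"):
        return None
    if setting == "balanced":
        n_pos = targets.sum()
        if n_pos == 0:
            return None
        return float((targets.size - n_pos) / n_pos)
    return float(setting)


@dataclass
class TrainConfig:
    """Desk-scale defaults; full-scale runs use kappa=200 and 500 epochs."""

    kappa: int = 32
    layers: int = 2
    # desk-scale learning rate; the full-scale configuration (kappa=200,
    # 500 epochs) uses 1e-3, which underfits badly at this problem size
    lr: float = 3e-3
    batch_size: int = 128
    epochs: int = 200                # combination-stage epochs (one step each)
    foundation_epochs: int = 1200
    foundation_queries: int = 512    # sampled 1-vs-all queries per foundation step
    dropout_embed: float = 0.1
    dropout_pred: float = 0.3
    weight_decay: float = 1e-5
    seed: int = 0
    stage: str = "combo"             # combo = frozen foundation; joint = fine-tune
    variant: str = "dual"
    psi: str = "multiply"
    aggregation: str = "mean"
    activation: str = "tanh"
    leaky_slope: float = 0.2
    virtual_init: str = "drug_mean"
    joint_lr_scale: float = 0.1
    max_neighbors: int = 200
    eval_every: int = 25
    channels: int = 32
    map_h: int = 4
    pos_weight: float | str = "balanced"  # upweight scarce positives in 1-vs-all BCE
    # pretraining scores these link types (encoding still uses every relation);
    # None/empty means all relations are scored
    foundation_query_relations: tuple = ("targets", "associated_with")
    dtype: str = "float32"  # training precision; eval stays deterministic

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise KGError("lr must be > 0, batch_size >= 1, epochs >= 1")
        if not (0 <= self.dropout_embed < 1 and 0 <= self.dropout_pred < 1):
            raise KGError("dropout rates must be in [0, 1)")
        if self.variant not in VARIANTS:
            raise KGError(f"unknown variant: {self.variant!r}")
        if self.stage not in ("foundation", "combo", "joint"):
            raise KGError(f"unknown stage: {self.stage!r}")

    def decoder_config(self) -> DecoderConfig:
        return DecoderConfig(
            kappa=self.kappa, channels=self.channels, map_h=self.map_h,
            dropout=self.dropout_pred,
        )


@dataclass
class Dataset:
    """A knowledge graph plus combination and indication labels."""

    kg: KnowledgeGraph                       # unaugmented; bio + membership + treats
    combinations: list[tuple[str, str, str]]
    truth_pairs: list[tuple[str, str]]       # (combo_id, disease_id)
    aug: KnowledgeGraph = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.aug is None:
            self.aug = prepare_kg(self.kg)
        self.diseases = [
            self.aug.vocab.names[i] for i in self.aug.vocab.of_type("disease")
        ]
        self.drugs_of = {cid: (a, b) for cid, a, b in self.combinations}

    @classmethod
    def from_synth(cls, cfg: SynthConfig) -> "Dataset":
        kg, combos, truth = generate(cfg)
        return cls(kg=kg, combinations=combos,
                   truth_pairs=[(c, s) for c, s, _ in truth.pairs])

    @classmethod
    def from_dir(cls, path) -> "Dataset":
        import os

        from .kg import load_triples
        from .synth import load_combinations, load_truth

        kg = load_triples(os.path.join(path, "triples.tsv"),
                          os.path.join(path, "types.tsv"))
        combos = load_combinations(os.path.join(path, "combinations.tsv"))
        truth = load_truth(os.path.join(path, "truth.tsv"))
        return cls(kg=kg, combinations=combos,
                   truth_pairs=[(c, s) for c, s, _ in truth.pairs])


# ------------------------------------------------------------- graph views

def _drop_relations(kg: KnowledgeGraph, names: set[str]) -> KnowledgeGraph:
    drop = {kg.relations.index[n] for n in names if n in kg.relations.index}
    drop |= {
        kg.relations.index[n + INVERSE_SUFFIX]
        for n in names if n + INVERSE_SUFFIX in kg.relations.index
    }
    return KnowledgeGraph(
        vocab=kg.vocab, relations=kg.relations,
        triples={t for t in kg.triples if t[1] not in drop},
    )


def biological_view(aug: KnowledgeGraph) -> KnowledgeGraph:
    """Biological triples only: no treats, no membership edges."""
    return _drop_relations(aug, {TREATS, CONTAINS_DRUG})


def structural_view(aug: KnowledgeGraph) -> KnowledgeGraph:
    """Everything except treats labels (membership edges kept)."""
    return _drop_relations(aug, {TREATS})


def pairs_to_triples(pairs, kg: KnowledgeGraph) -> set[tuple[int, int, int]]:
    """(combo, disease) label pairs as augmented treats triples (both directions)."""
    r = kg.relations.index[TREATS]
    r_inv = kg.relations.index.get(TREATS + INVERSE_SUFFIX)
    out: set[tuple[int, int, int]] = set()
    for c, s in pairs:
        h, t = kg.vocab.index[c], kg.vocab.index[s]
        out.add((h, r, t))
        if r_inv is not None:
            out.add((t, r_inv, h))
    return out


# -------------------------------------------------------- foundation stage

class FoundationModel:
    """Relational encoder + shared decoder trained by 1-vs-all link prediction."""

    def __init__(self, kg: KnowledgeGraph, config: TrainConfig, seed: int | None = None):
        self.kg = kg
        self.config = config
        self._dt = np.dtype(config.dtype).type
        seed = config.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        init_rng, self.drop_rng, self.sample_rng = [
            np.random.default_rng(s) for s in ss.spawn(3)
        ]
        with ad.dtype(self._dt):
            self.struct = GraphTensors(kg, aggregation=config.aggregation)
            k = config.kappa
            self.params: dict[str, Tensor] = {
                "entity_emb": ad.param(ad.xavier_normal(init_rng, (kg.n_entities, k))),
                "relation_emb": ad.param(ad.xavier_normal(init_rng, (kg.n_relations, k))),
            }
            for layer in range(config.layers):
                for w in ("W_orig", "W_inv", "W_self", "W_rel"):
                    self.params[f"l{layer}_{w}"] = ad.param(
                        ad.xavier_normal(init_rng, (k, k))
                    )
            self.decoder = Decoder(
                config.decoder_config(), seed=int(ss.generate_state(1)[0] % 2**31)
            )
        for name, t in self.decoder.params.items():
            self.params[f"dec_{name}"] = t
        self._build_queries()
        self.history: dict[str, list[float]] = {"loss": []}

    def _build_queries(self) -> None:
        allowed = None
        names = self.config.foundation_query_relations
        if names:
            allowed = set()
            for n in names:
                for full in (n, n + INVERSE_SUFFIX):
                    if full in self.kg.relations.index:
                        allowed.add(self.kg.relations.index[full])
        by_query: dict[tuple[int, int], list[int]] = {}
        for h, r, t in sorted(self.kg.triples):
            if allowed is not None and r not in allowed:
                continue
            by_query.setdefault((h, r), []).append(t)
        if not by_query:  # fall back to scoring everything
            for h, r, t in sorted(self.kg.triples):
                by_query.setdefault((h, r), []).append(t)
        self.q_heads = np.array([q[0] for q in by_query], dtype=np.int64)
        self.q_rels = np.array([q[1] for q in by_query], dtype=np.int64)
        rows, cols = [], []
        for qi, tails in enumerate(by_query.values()):
            rows.extend([qi] * len(tails))
            cols.extend(tails)
        self.q_targets = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(by_query), self.kg.n_entities),
        )

    def encode(self, training: bool = False) -> tuple[Tensor, Tensor]:
        cfg = self.config
        H: Tensor = self.params["entity_emb"]
        R: Tensor = self.params["relation_emb"]
        for layer in range(cfg.layers):
            p = {w: self.params[f"l{layer}_{w}"] for w in ("W_orig", "W_inv", "W_self", "W_rel")}
            H, R = layer_forward_t(
                self.struct, H, R, p, cfg.psi, cfg.activation,
                dropout=cfg.dropout_embed, training=training, rng=self.drop_rng,
            )
        return H, R

    def step(self, query_idx: np.ndarray, opt: Adam) -> float:
        with ad.dtype(self._dt):
            return self._step(query_idx, opt)

    def _step(self, query_idx: np.ndarray, opt: Adam) -> float:
        H, R = self.encode(training=True)
        nV, nR = self.kg.n_entities, self.kg.n_relations
        HI = ad.spmm(ad.rows_onehot(self.q_heads[query_idx], nV), H)
        HR = ad.spmm(ad.rows_onehot(self.q_rels[query_idx], nR), R)
        scores = self.decoder.score_against(
            HI, HR, H, training=True, rng=self.drop_rng
        )
        targets = np.asarray(self.q_targets[query_idx].todense())
        loss = ad.bce_with_logits(
            scores, targets, pos_weight=_pos_weight(targets, self.config.pos_weight)
        )
        if not np.isfinite(loss.data):
            raise KGError("training diverged: non-finite loss")
        opt.zero_grad()
        loss.backward()
        opt.step()
        return float(loss.data)

    def fit(self, epochs: int | None = None, queries_per_epoch: int | None = None) -> list[float]:
        cfg = self.config
        epochs = cfg.foundation_epochs if epochs is None else epochs
        qpe = cfg.foundation_queries if queries_per_epoch is None else queries_per_epoch
        opt = Adam(self.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
        nq = len(self.q_heads)
        for _ in range(epochs):
            idx = (
                self.sample_rng.choice(nq, size=qpe, replace=False)
                if qpe < nq else np.arange(nq)
            )
            self.history["loss"].append(self.step(idx, opt))
        return self.history["loss"]

    def final_state(self) -> EmbeddingState:
        with ad.dtype(self._dt):
            H, R = self.encode(training=False)
        return EmbeddingState(
            H.data.astype(np.float64), R.data.astype(np.float64), self.config.layers
        )


def train_foundation(kg: KnowledgeGraph, config: TrainConfig) -> tuple[EmbeddingState, FoundationModel]:
    """Pretrain embeddings on an augmented graph; returns final state + model."""
    model = FoundationModel(kg, config)
    model.fit()
    return model.final_state(), model


# ------------------------------------------------------- combination stage

def _node_init_matrix(batch: SubgraphBatch, n_entities: int, virtual_init: str) -> sp.csr_matrix:
    """Sparse (n_nodes, |V|) mapping entity embeddings to initial node features.

    Real nodes gather their own row; virtual rows average the two drugs.
    """
    rows, cols, vals = [], [], []
    for i, g in enumerate(batch.node_global):
        if g >= 0 and i not in batch.virtual_rows:
            rows.append(i)
            cols.append(int(g))
            vals.append(1.0)
    if virtual_init == "drug_mean":
        for sg, vrow in zip(batch.subgraphs, batch.virtual_rows):
            rows += [vrow, vrow]
            cols += [sg.drug_a_idx, sg.drug_b_idx]
            vals += [0.5, 0.5]
    return sp.csr_matrix((vals, (rows, cols)), shape=(batch.n_nodes, n_entities))


class ComboModel:
    """Attention subgraph encoder + decoder over disease candidates."""

    def __init__(
        self,
        config: TrainConfig,
        n_entities: int,
        n_relations: int,
        disease_idx: np.ndarray,
        treats_rel: int,
        foundation_state: EmbeddingState | None,
        trainable_embeddings: bool = False,
        trainable_disease_tails: bool = True,
        seed: int | None = None,
        decoder_init: dict | None = None,
    ):
        self.config = config
        self._dt = np.dtype(config.dtype).type
        self.n_entities, self.n_relations = n_entities, n_relations
        self.disease_idx = np.asarray(disease_idx, dtype=np.int64)
        self.trainable_embeddings = trainable_embeddings
        seed = config.seed if seed is None else seed
        ss = np.random.SeedSequence(seed + 101)
        init_rng, self.drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        with ad.dtype(self._dt):
            self._build_params(init_rng, ss, foundation_state, treats_rel, decoder_init,
                               trainable_embeddings, trainable_disease_tails)

    def _build_params(self, init_rng, ss, foundation_state, treats_rel, decoder_init,
                      trainable_embeddings, trainable_disease_tails) -> None:
        config = self.config
        n_entities, n_relations = self.n_entities, self.n_relations
        k = config.kappa
        self.params: dict[str, Tensor] = {}
        for layer in range(config.layers):
            self.params[f"a{layer}_w_att"] = ad.param(ad.xavier_normal(init_rng, (k, 1)))
            self.params[f"a{layer}_W_lam"] = ad.param(ad.xavier_normal(init_rng, (k, k)))
            self.params[f"a{layer}_W_o"] = ad.param(ad.xavier_normal(init_rng, (k, k)))
        if foundation_state is not None:
            emb0 = foundation_state.entity_emb
            rel0 = foundation_state.relation_emb
            treats_init = rel0[treats_rel].copy()
        else:
            emb0 = ad.xavier_normal(init_rng, (n_entities, k))
            rel0 = ad.xavier_normal(init_rng, (n_relations, k))
            treats_init = rel0[treats_rel].copy()
        if trainable_embeddings:
            self.params["entity_emb"] = ad.param(emb0)
            self.params["relation_emb"] = ad.param(rel0)
        else:
            self._entity_const = ad.constant(emb0)
            self._relation_const = ad.constant(rel0)
        # disease embeddings enter only as decoder tails (never inside
        # subgraphs), so they can be calibrated during this stage without
        # breaking the frozen, inductive subgraph encoder
        self.trainable_disease_tails = trainable_disease_tails and not trainable_embeddings
        if self.trainable_disease_tails:
            self.params["disease_emb"] = ad.param(emb0[self.disease_idx].copy())
        self.params["treats_emb"] = ad.param(treats_init[None, :])
        self.decoder = Decoder(config.decoder_config(), seed=int(ss.generate_state(1)[0] % 2**31))
        if decoder_init is not None:
            # shared decoder: continue from the foundation-trained scorer
            self.decoder.load_state_dict(decoder_init)
        for name, t in self.decoder.params.items():
            self.params[f"dec_{name}"] = t
        self.history: dict[str, list] = {"loss": [], "valid_mrr": []}

    # -- tensors -----------------------------------------------------------
    def _entities(self) -> Tensor:
        return self.params["entity_emb"] if self.trainable_embeddings else self._entity_const

    def _relations(self) -> Tensor:
        return self.params["relation_emb"] if self.trainable_embeddings else self._relation_const

    def combo_embeddings(self, batch: SubgraphBatch, training: bool = False) -> Tensor:
        cfg = self.config
        M = _node_init_matrix(batch, self.n_entities, cfg.virtual_init)
        X = ad.spmm(M, self._entities())
        R = self._relations()
        for layer in range(cfg.layers):
            p = {
                "w_att": self.params[f"a{layer}_w_att"],
                "W_lam": self.params[f"a{layer}_W_lam"],
                "W_o": self.params[f"a{layer}_W_o"],
            }
            X = attention_layer_t(
                batch, X, R, p, cfg.psi, cfg.activation, cfg.leaky_slope,
                dropout=cfg.dropout_embed, training=training, rng=self.drop_rng,
            )
        V = ad.rows_onehot(np.array(batch.virtual_rows), batch.n_nodes)
        return ad.spmm(V, X)

    def disease_scores(self, batch: SubgraphBatch, training: bool = False) -> Tensor:
        with ad.dtype(self._dt):
            return self._disease_scores(batch, training)

    def _disease_scores(self, batch: SubgraphBatch, training: bool) -> Tensor:
        HI = self.combo_embeddings(batch, training=training)
        n = HI.data.shape[0]
        HR = ad.matmul(ad.constant(np.ones((n, 1))), self.params["treats_emb"])
        if self.trainable_disease_tails:
            H_dis = self.params["disease_emb"]
        else:
            H_dis = ad.spmm(
                ad.rows_onehot(self.disease_idx, self.n_entities), self._entities()
            )
        return self.decoder.score_against(
            HI, HR, H_dis, training=training, rng=self.drop_rng
        )

    # -- training ----------------------------------------------------------
    def snapshot(self) -> dict:
        return {
            "params": {k: v.data.copy() for k, v in self.params.items()},
            "bn": (self.decoder.running_mean.copy(), self.decoder.running_var.copy()),
        }

    def restore(self, snap: dict) -> None:
        for k, v in snap["params"].items():
            self.params[k].data = v.copy()
        self.decoder.running_mean, self.decoder.running_var = (
            snap["bn"][0].copy(), snap["bn"][1].copy()
        )


def train_combo(
    config: TrainConfig,
    model: ComboModel,
    train_batch: SubgraphBatch,
    train_targets: np.ndarray,
    valid_eval=None,
) -> ComboModel:
    """Optimise the combination stage, checkpointing by validation MRR.

    ``valid_eval`` is a callable (model -> float MRR) run on an evaluation
    schedule; the best-scoring parameter snapshot is restored at the end.
    """
    if train_targets.sum() == 0:
        raise KGError("no treats triples to train on")
    scales = {}
    if config.stage == "joint":
        # fine-tune the foundation-derived embedding tables at a reduced rate
        scales = {"entity_emb": config.joint_lr_scale, "relation_emb": config.joint_lr_scale}
    opt = Adam(model.params, lr=config.lr, weight_decay=config.weight_decay,
               lr_scales=scales)
    best = (-np.inf, None)
    pw = _pos_weight(train_targets, config.pos_weight)
    for epoch in range(1, config.epochs + 1):
        scores = model.disease_scores(train_batch, training=True)
        loss = ad.bce_with_logits(scores, train_targets, pos_weight=pw)
        if not np.isfinite(loss.data):
            raise KGError("training diverged: non-finite loss")
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.history["loss"].append(float(loss.data))
        if valid_eval is not None and (
            epoch == 1 or epoch % config.eval_every == 0 or epoch == config.epochs
        ):
            mrr = valid_eval(model)
            model.history["valid_mrr"].append((epoch, mrr))
            if mrr > best[0]:
                best = (mrr, model.snapshot())
    if best[1] is not None:
        model.restore(best[1])
    return model


# ------------------------------------------------------------ full pipeline

class Pipeline:
    """A trained variant exposing eval-mode disease scores per combination."""

    def __init__(self, variant: str, config: TrainConfig, dataset: Dataset, split: Split):
        self.variant = variant
        self.config = config
        self.dataset = dataset
        self.split = split
        self.foundation_state: EmbeddingState | None = None
        self.combo_model: ComboModel | None = None
        self.onelayer_model: FoundationModel | None = None
        self.subgraphs: dict[str, object] = {}
        self._score_cache: dict[str, np.ndarray] = {}
        self._known_treats: set[tuple[int, int, int]] = set()

    # -- scoring -----------------------------------------------------------
    def disease_scores(self, combo_id: str) -> np.ndarray:
        if combo_id not in self._score_cache:
            if self.variant == "onelayer":
                self._cache_onelayer_scores()
            else:
                self._cache_subgraph_scores([combo_id])
        if combo_id not in self._score_cache:
            raise KGError(f"unknown combination: {combo_id}")
        return self._score_cache[combo_id]

    def _cache_subgraph_scores(self, combo_ids: list[str]) -> None:
        ids = [c for c in combo_ids if c in self.subgraphs and c not in self._score_cache]
        if not ids:
            return
        batch = SubgraphBatch([self.subgraphs[c] for c in ids], self.dataset.aug.n_relations)
        scores = self.combo_model.disease_scores(batch, training=False).data
        for i, c in enumerate(ids):
            self._score_cache[c] = scores[i]

    def _cache_onelayer_scores(self) -> None:
        model = self.onelayer_model
        state = model.final_state()
        kg = self.dataset.aug
        combo_rows = np.array([kg.vocab.index[c] for c, _, _ in self.dataset.combinations])
        dis_rows = np.array([kg.vocab.index[d] for d in self.dataset.diseases])
        r_treats = kg.relations.index[TREATS]
        HI = ad.constant(state.entity_emb[combo_rows])
        HR = ad.constant(np.tile(state.relation_emb[r_treats], (len(combo_rows), 1)))
        H_dis = ad.constant(state.entity_emb[dis_rows])
        scores = model.decoder.score_against(HI, HR, H_dis).data
        for i, (c, _, _) in enumerate(self.dataset.combinations):
            self._score_cache[c] = scores[i]

    def predict(self, drug_a: str, drug_b: str, top_k: int = 10) -> list[tuple[str, float]]:
        """Rank diseases for an arbitrary (possibly novel) drug pair."""
        kg = self.dataset.aug
        if self.variant == "onelayer":
            state = self.onelayer_model.final_state()
            ia, ib = kg.vocab.index[drug_a], kg.vocab.index[drug_b]
            hi = 0.5 * (state.entity_emb[ia] + state.entity_emb[ib])
            dis_rows = np.array([kg.vocab.index[d] for d in self.dataset.diseases])
            scores = self.onelayer_model.decoder.score_against(
                ad.constant(hi[None, :]),
                ad.constant(state.relation_emb[kg.relations.index[TREATS]][None, :]),
                ad.constant(state.entity_emb[dis_rows]),
            ).data[0]
        else:
            sg = build_subgraph(
                kg, drug_a, drug_b,
                known_treats=self._known_treats, exclude=set(),
                max_neighbors=self.config.max_neighbors, seed=self.config.seed,
            )
            batch = SubgraphBatch([sg], kg.n_relations)
            scores = self.combo_model.disease_scores(batch, training=False).data[0]
        order = np.argsort(-scores, kind="stable")[:top_k]
        return [(self.dataset.diseases[i], float(scores[i])) for i in order]

    def metrics(self, pairs, ground_truth=None) -> RankingResult:
        gt = set(ground_truth) if ground_truth is not None else set(self.dataset.truth_pairs)
        if self.variant != "onelayer":
            self._cache_subgraph_scores(sorted({c for c, _ in pairs}))
        return evaluate_scores(self.disease_scores, pairs, self.dataset.diseases, gt)


def train_pipeline(
    dataset: Dataset,
    split: Split,
    config: TrainConfig,
    pretrained: tuple[EmbeddingState, dict] | None = None,
) -> Pipeline:
    """Train the configured variant end to end and return a scoring pipeline.

    ``pretrained`` optionally supplies a (foundation state, decoder state)
    pair so one foundation — which depends only on the biological graph,
    never on the split — can be shared across splits and tasks.
    """
    variant = config.variant
    pipe = Pipeline(variant, config, dataset, split)
    aug = dataset.aug
    train_triples = pairs_to_triples(split.train, aug)
    pipe._known_treats = train_triples

    if variant == "onelayer":
        merged = structural_view(aug)
        merged = KnowledgeGraph(
            vocab=merged.vocab, relations=merged.relations,
            triples=set(merged.triples) | train_triples,
        )
        d = asdict(config)
        if config.foundation_query_relations:
            d["foundation_query_relations"] = tuple(
                config.foundation_query_relations
            ) + (TREATS, CONTAINS_DRUG)
        model = FoundationModel(merged, TrainConfig(**d))
        model.fit(epochs=config.foundation_epochs + config.epochs // 4)
        pipe.onelayer_model = model
        pipe.foundation_state = model.final_state()
        return pipe

    # subgraphs for every combination, with each combo's own labels excluded
    subgraphs = batch_build(
        aug, dataset.combinations, known_treats=train_triples,
        policy="exclude_query_treats", max_neighbors=config.max_neighbors,
        seed=config.seed,
    )
    pipe.subgraphs = {sg.combo_id: sg for sg in subgraphs}

    foundation_state = None
    decoder_init = None
    if variant == "dual":
        if pretrained is not None:
            foundation_state, decoder_init = pretrained
        else:
            bio = biological_view(aug)
            foundation_state, fmodel = train_foundation(bio, config)
            decoder_init = fmodel.decoder.state_dict()
        pipe.foundation_state = foundation_state

    disease_idx = np.array([aug.vocab.index[d] for d in dataset.diseases])
    model = ComboModel(
        config, aug.n_entities, aug.n_relations, disease_idx,
        aug.relations.index[TREATS], foundation_state,
        trainable_embeddings=(variant == "subgraph_only" or config.stage == "joint"),
        decoder_init=decoder_init,
    )

    train_combos = sorted({c for c, _ in split.train})
    valid_combos = sorted({c for c, _ in split.valid})
    dis_col = {d: i for i, d in enumerate(dataset.diseases)}
    train_batch = SubgraphBatch(
        [pipe.subgraphs[c] for c in train_combos], aug.n_relations
    )
    targets = np.zeros((len(train_combos), len(dataset.diseases)))
    row = {c: i for i, c in enumerate(train_combos)}
    for c, s in split.train:
        targets[row[c], dis_col[s]] = 1.0

    valid_gt = set(split.train) | set(split.valid)
    valid_batch = (
        SubgraphBatch([pipe.subgraphs[c] for c in valid_combos], aug.n_relations)
        if valid_combos else None
    )

    def valid_eval(m: ComboModel) -> float:
        if valid_batch is None or not split.valid:
            return 0.0
        scores = m.disease_scores(valid_batch, training=False).data
        srow = {c: i for i, c in enumerate(valid_combos)}
        res = evaluate_scores(
            lambda c: scores[srow[c]], split.valid, dataset.diseases, valid_gt
        )
        return res.mrr

    train_combo(config, model, train_batch, targets, valid_eval=valid_eval)
    pipe.combo_model = model
    return pipe


def build_variant(variant: str, dataset: Dataset, split: Split, config: TrainConfig) -> Pipeline:
    """Dispatch on the ablation variant name."""
    if variant not in VARIANTS:
        raise KGError(f"unknown variant: {variant!r}")
    d = asdict(config)
    d["variant"] = variant
    return train_pipeline(dataset, split, TrainConfig(**d))
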