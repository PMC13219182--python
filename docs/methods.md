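# Methods

## The model

`combokg` predicts disease indications for drug combinations from a
heterogeneous biomedical knowledge graph using a dual-layer architecture:

1. **Foundation layer.** A composition-based relational GNN (CompGCN-style)
   over the biological graph G = (V, E, R). Entity and relation embeddings
   (dimension κ) are Xavier-normal initialised. Each convolution computes,
   for entity i,

       h_i ← f( agg_{(j,r) ∈ N(i)} W_dir(r) ψ(h_j, h_r) + W_self h_i ),
       h_r ← W_rel h_r,

   with ψ ∈ {subtract, multiply, circular correlation} (default multiply),
   W_dir shared per edge direction (original / inverse / self-loop) rather
   than per relation — relation identity enters through ψ — and f = tanh.
   Inverse relations are materialised so messages flow both ways; the
   self-loop is realised by the W_self term, not by explicit triples. The
   aggregation is a degree-normalised mean by default (`aggregation: sum`
   restores the plain sum in the update equation); means keep hub-node
   activations at a stable scale at desk sizes.

2. **Combination layer.** Each drug pair is represented by a virtual
   combination node connected to both constituent drugs through a dedicated
   `contains_drug` relation. Its subgraph is the induced two-hop
   neighborhood of the virtual node over the augmented graph, with all of
   the query combination's own `treats` edges excluded (the
   `exclude_query_treats` policy) so a combination can never see its own
   labels. An attention GNN then updates every subgraph node:

       α_{u,r} = softmax_{(u,r) ∈ N(v)} LeakyReLU(w_att · ψ(h_u, h_r)),
       e_v = f( Σ α_{u,r} ψ(h_u, h_r) ),   h_v ← f( W_λ e_v + W_o h_v ),

   reading out the virtual node after two layers. The virtual node starts
   from the mean of its two drugs' foundation embeddings (configurable to
   zeros); neighbor sums run in canonical sorted edge order so swapping the
   drugs gives a bit-identical embedding.

3. **Decoder.** An InteractE-style convolutional scorer: head and relation
   embeddings are interleaved into a checkered 2-D map, circularly
   convolved with a kernel bank, batch-normalised, ReLU-activated,
   flattened, projected back to κ, and dotted with the tail embedding.
   Predictions are σ(S); training minimises 1-vs-all binary cross-entropy
   over all candidate tails with Adam and decoupled L2 weight decay.

## Training procedure

**Stage 1 (foundation)** trains embeddings, convolution weights and decoder
by link prediction on the biological graph. Every optimisation step encodes
the full graph and scores a sampled batch of (head, relation) queries
against all entities. Two departures from the naive setup proved necessary
at desk scale and are configurable back:

- *Balanced positives* (`pos_weight: balanced`). With ~960 candidate tails
  and a handful of positives per query, plain mean BCE is minimised by
  scoring everything negative; the embeddings then carry no signal.
  Weighting positive cells by the negative/positive count ratio restores
  learning. `pos_weight: 1` gives the plain objective.
- *Scored relations* (`foundation_query_relations`). The encoder
  message-passes over every relation, but 1-vs-all queries are scored only
  for drug–target and gene–disease links by default. The synthetic graph's
  remaining relations are uniform random and therefore incompressible at
  rank κ; scoring them consumes the embedding capacity that the
  transferable gene–disease factorisation needs (measured: gene–disease
  link MRR ≈ 0.06 when all relations are scored vs ≈ 0.4 when restricted,
  at identical budgets). An empty tuple scores all relations.

**Stage 2 (combination)** freezes the encoded foundation state, builds the
leakage-filtered subgraph of every known combination once, and trains the
attention layers, the decoder (continuing from the stage-1 decoder), a
`treats` relation embedding, and a trainable copy of the disease tail
embeddings under 1-vs-all BCE over diseases. Disease vectors appear only as
decoder tails — two-hop combination subgraphs contain drugs, their targets
and neighboring combinations, never diseases — so tuning them cannot leak
into the inductive subgraph encoder, which remains a pure function of
frozen quantities and learned aggregation weights. The checkpoint with the
best validation filtered MRR (evaluated on a schedule) is kept.
`stage: joint` instead fine-tunes the foundation-derived embedding tables
at `joint_lr_scale` × the learning rate.

**Variants.** `dual` is the full two-stage model. `onelayer` merges
membership and training `treats` edges into one graph and trains the
foundation encoder + decoder on it directly (no attention layer; unseen
combinations are scored from their encoded entity row, or the mean of their
drugs' rows when absent). `subgraph_only` skips pretraining entirely and
trains Xavier-initialised embeddings through the subgraph encoder alone.

## Evaluation protocol

Transductive splits shuffle (combination, disease) pairs 60/20/20 and
guarantee every held-out combination is seen in training. Inductive splits
set aside ≥ 20% of combinations such that test combinations share no
constituent drug with the rest (connected components of the drug-sharing
graph, smallest first; an error advises regeneration when the graph is too
connected). For each test triple all diseases are enumerated as candidates,
other known-true diseases of the same combination are removed (filtered
setting), and ties receive mean rank, so a constant scorer earns the
analytic random expectation H_n/n rather than rank 1. Hits@N and MRR
average per query; AUROC/AUPR pool all unfiltered (query, candidate) pairs.
Skipped queries (no buildable subgraph) are counted and reported, never
silently dropped.

## Synthetic benchmark

The generator emulates a drug-repurposing knowledge graph: five entity
types (100 drugs, 600 genes, 150 diseases, 40 pathways, 80 phenotypes),
eight biological relations totalling ~15,000 uniformly sampled edges, and
120 drug-pair combinations. Combinations pair drugs within ten
therapeutic-class groups; uniform pairing would fuse the drug-sharing graph
into one component and make drug-disjoint inductive folds impossible.
An indication is planted between combination (d1, d2) and disease s exactly
when the union of the drugs' target genes hits s's gene module in ≥ k_mech
= 2 genes *and* each drug hits the module individually — so single-drug
neighborhoods cannot explain the labels. Planted indications are kept with
probability 1 − ε and ~ε of the final label set is uniform noise
(ε = 0.05). The defaults yield ~1,200 indications (~10 per combination).

What the generator does not emulate: scale-free degree structure, correlated
pathway/module organisation, relation-type semantics beyond typed endpoints,
and textual evidence quality. Passing tests on it demonstrate that the
implementation recovers a planted mechanism under controlled conditions,
not that the model attains any particular accuracy on real biomedical data.

## Numerical choices

- Training arithmetic runs in float32 (1 CPU throughput; `dtype` config);
  gradient-check tests and eval-mode scoring run in float64. Results are
  deterministic for a fixed seed either way.
- Desk-scale defaults: κ = 32, 2 layers each stage, 32 decoder channels on
  a 4×16 checkered map, learning rate 3e-3, 1,200 foundation steps of 512
  sampled queries, 200 combination epochs, dropout 0.1 (embedding) / 0.3
  (prediction), weight decay 1e-5. The full-scale configuration
  (κ = 200, η = 1e-3, 500 epochs) used on real biomedical graphs with
  tens of thousands of entities is out of desk reach; at κ = 32 the 1e-3
  rate demonstrably underfits, which is why 3e-3 is the desk default.
- BCE probabilities are clamped at 1e-12 before logarithms; the logit-space
  loss uses the softplus form and never overflows.
- Ties in ranking use mean rank; subgraph neighbor caps (default 200)
  sample uniformly with per-combination derived seeds; all randomness
  descends from a single integer seed via numpy SeedSequence.

## Known limitations

- At κ = 32 on the default benchmark the dual model reaches a 3-seed mean
  held-out filtered MRR of ≈ 0.11 transductive (≈ 3× the 0.037 random
  baseline; Hits@10 ≈ 0.24) and ≈ 0.07 inductive (≈ 1.8× random). Probes
  show this sits at the information ceiling of the architecture's pathway:
  an optimal linear decode of summed foundation gene-embeddings reaches MRR
  ≈ 0.14, and even ridge regression on the true 600-dimensional binary
  target-gene features with label supervision reaches only MRR ≈ 0.17 /
  Hits@10 ≈ 0.31. Exceeding that requires a near-optimal rank-κ
  factorisation of the full gene–disease incidence plus explicit both-drug
  (AND) aggregation, which label supervision over ~100 training
  combinations does not recover.
- The ablation gap between variants is within seed noise at desk scale;
  the dual model tops the table but `onelayer` vs `subgraph_only` ordering
  is unstable.
- The RotatE scorer is provided as a baseline scoring function only; no
  RotatE training loop is included.
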