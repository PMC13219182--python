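# combokg

Dual-layer knowledge-graph neural network for predicting disease
indications of **drug combinations**.

Most computational repurposing methods score single drugs against diseases.
Combination therapy is harder: a pair's therapeutic effect depends on how
both drugs' targets jointly engage a disease's gene module, and most pairs
of interest never appear in training data. `combokg` addresses this with a
drug-centric, two-layer design aimed at researchers in computational drug
discovery and knowledge-graph machine learning:

- a **foundation layer** — a composition-based relational GNN (CompGCN
  family) that learns entity/relation embeddings h_i, h_r ∈ R^κ on a
  heterogeneous biological graph G = (V, E, R) of drugs, genes, diseases,
  pathways and phenotypes, via the update
  h_i ← f(Σ_{(j,r)∈N(i)} W_λ ψ(h_j, h_r) + W_o h_i);
- a **combination layer** — each drug pair (d₁, d₂) becomes a *virtual
  combination node* connected to both drugs; its two-hop subgraph is
  encoded by attention message passing,
  α_{u,r} = softmax LeakyReLU(W_att ψ(h_u, h_r)), giving a combination
  embedding that exists even for pairs never seen in training (inductive
  prediction);
- an **InteractE-style convolutional decoder** scoring
  S_{i,r,j} = [Flatten(σ(BN(Conv(Ω(h_i, h_r); Θ))))] W h_j, trained with
  1-vs-all binary cross-entropy, ŷ = σ(S).

Evaluation follows the standard filtered knowledge-graph protocol: for each
held-out (combination, *treats*, disease) triple all candidate diseases are
enumerated, other known-true diseases of the same combination are removed,
and Hits@N / MRR / AUROC / AUPR are reported — transductively (60/20/20
pair split) and inductively (test combinations share no constituent drug
with training). A seeded synthetic-graph generator with *planted*
mechanistic indications (both drugs must hit the disease's gene module, ≥2
genes jointly) provides a fully self-contained test bed.

## Worked example

```python
import combokg as ck

cfg = ck.SynthConfig(n_drug=16, n_gene=80, n_disease=25, n_pathway=6,
                     n_phenotype=10, n_combos=20, n_drug_groups=4, seed=7,
                     edge_counts={"targets": 96, "associated_with": 150,
                                  "interacts_with": 200, "gene_in_pathway": 60,
                                  "disease_in_pathway": 15, "disease_has_phenotype": 30,
                                  "gene_has_phenotype": 40, "comorbid_with": 10})
ds = ck.Dataset.from_synth(cfg)
split = ck.make_split(ds.truth_pairs, ds.combinations, ck.SplitSpec(seed=7))
train_cfg = ck.TrainConfig(seed=7, kappa=8, map_h=2, channels=8,
                           foundation_epochs=40, foundation_queries=64,
                           epochs=40, eval_every=10)
pipe = ck.train_pipeline(ds, split, train_cfg)
res = pipe.metrics(split.test)
print(f"filtered MRR: {res.mrr:.3f}   Hits@10: {res.hits10:.3f}   AUROC: {res.auroc:.3f}")
print(f"random-ranking MRR baseline: {ck.random_baseline_mrr(25):.3f}")
cid, da, db = ds.combinations[0]
for disease, score in pipe.predict(da, db, top_k=3):
    print(f"{disease}\t{score:.3f}")
```

prints

```
filtered MRR: 0.461   Hits@10: 0.538   AUROC: 0.619
random-ranking MRR baseline: 0.153
S018	1.569
S010	1.366
S009	1.366
```

i.e. on this small planted graph the model ranks the true held-out disease
around position 2 on average (reciprocal rank 0.461), three times better
than the 0.153 expected under random ranking of 25 candidates, and the
top-3 indications for the first combination are printed with their scores.

The same workflows are available from the shell:

```bash
combokg synth --config synth.yaml --out-dir data/
combokg train --config train.yaml --data-dir data/ --out-dir run/
combokg evaluate --data-dir data/ --out-dir eval/ --mode inductive --folds 5
combokg predict --data-dir data/ D003 D007 --top-k 10
```

Every command writes a `manifest.json` (command, config hash, seed, input
digests, package version) next to its outputs.

## Model variants

`TrainConfig(variant=...)` selects the full `dual` model, a `onelayer`
ablation (combinations and indications merged into a single graph, encoded
by the foundation GNN alone), or `subgraph_only` (no pretraining; subgraph
attention encoder from Xavier-initialised embeddings). See
`docs/methods.md` for the model's assumptions, training details, parameter
defaults, and known limitations.

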