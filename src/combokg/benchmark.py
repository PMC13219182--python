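"""Standard evaluation runs on the default synthetic benchmark.

One foundation is pretrained per seed on the biological graph (which never
depends on a split) and shared by the transductive dual run, the inductive
dual run, and the ablation variants for that seed.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from .ranking import SplitSpec, make_split, random_baseline_mrr
from .synth import SynthConfig
from .train import (
    Dataset,
    TrainConfig,
    biological_view,
    train_foundation,
    train_pipeline,
)


def run_seed(seed: int, overrides: dict | None = None) -> dict:
    """All standard runs for one seed: dual (both tasks) plus ablations."""
    ds = Dataset.from_synth(SynthConfig(seed=seed))
    cfg = TrainConfig(seed=seed, **(overrides or {}))
    fstate, fmodel = train_foundation(biological_view(ds.aug), cfg)
    pretrained = (fstate, fmodel.decoder.state_dict())
    tspl = make_split(ds.truth_pairs, ds.combinations, SplitSpec(seed=seed))
    ispl = make_split(
        ds.truth_pairs, ds.combinations, SplitSpec(mode="inductive", seed=seed)
    )
    out: dict = {"seed": seed}
    runs = [
        ("dual_transductive", "dual", tspl),
        ("dual_inductive", "dual", ispl),
        ("onelayer_transductive", "onelayer", tspl),
        ("subgraph_only_transductive", "subgraph_only", tspl),
    ]
    for key, variant, spl in runs:
        d = asdict(cfg)
        d["variant"] = variant
        pipe = train_pipeline(ds, spl, TrainConfig(**d), pretrained=pretrained)
        r = pipe.metrics(spl.test)
        out[key] = r.to_dict()
    out["n_diseases"] = len(ds.diseases)
    out["n_treats_pairs"] = len(ds.truth_pairs)
    return out


def run_benchmark(seeds: list[int], overrides: dict | None = None) -> dict:
    """Per-seed runs plus 3-seed (or n-seed) means of the headline metrics."""
    per_seed = [run_seed(s, overrides) for s in seeds]
    summary: dict = {"seeds": list(seeds), "per_seed": per_seed}
    for key in ("dual_transductive", "dual_inductive",
                "onelayer_transductive", "subgraph_only_transductive"):
        for metric in ("mrr", "hits10", "hits1", "auroc", "aupr"):
            vals = [s[key][metric] for s in per_seed if s[key][metric] is not None]
            if vals:
                summary[f"{key}_{metric}"] = float(np.mean(vals))
    summary["random_baseline_mrr"] = random_baseline_mrr(per_seed[0]["n_diseases"])
    return summary
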