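"""Synthetic end-to-end benchmarks.

The block benchmark generates the default block-model dataset, fits the
full stratified model and the no-stratification baseline on identical
splits and negatives, and reports held-out test AP for both plus the
within-group minus between-group cosine-similarity gap of the pretrained
compound embeddings. The reaction benchmark does the same for the
three-view reaction-feature model on the induced compound-enzyme table.

Problem sizes (80 x 80 entities, 4 groups, 50 contrastive and 30 predictor
epochs, batch size 8, temperature 0.07) are the package's desk-scale
defaults: large enough for the contrastive signal to separate groups,
small enough to run on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import BaselineModel, CSIModel, ReactionCSIModel
from .pipeline import TrainConfig
from .simulate import BlockModelConfig, ReactionModelConfig, generate_block_dataset, generate_reaction_dataset

BENCHMARK_CONFIG = TrainConfig(
    phase1_epochs=50,
    phase2_epochs=30,
    baseline_epochs=30,
    batch_size=8,
    temperature=0.07,
    test_neg_ratio=1,
    L_max=128,
)


def cosine_group_gap(embeddings: dict[str, np.ndarray], groups: dict[str, int]) -> dict:
    """Mean within-group minus mean between-group cosine similarity."""
    ids = sorted(embeddings)
    Z = np.stack([embeddings[i] for i in ids])
    Z = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    cos = Z @ Z.T
    g = np.array([groups[i] for i in ids])
    same = g[:, None] == g[None, :]
    off = ~np.eye(len(ids), dtype=bool)
    within = float(cos[same & off].mean())
    between = float(cos[~same].mean())
    return {"within": within, "between": between, "gap": within - between}


def run_block_benchmark(seeds=(0, 1, 2), block_config: BlockModelConfig | None = None,
                        train_config: TrainConfig | None = None) -> dict:
    """CSI vs baseline on the block-model dataset, one replicate per seed."""
    train_config = train_config or BENCHMARK_CONFIG
    out = {"seeds": list(seeds), "csi_ap": [], "baseline_ap": [],
           "cosine_gap": [], "csi_reports": [], "baseline_reports": []}
    for seed in seeds:
        cfg = block_config or BlockModelConfig(seed=seed)
        table, compounds, sequences, (cgroups, _) = generate_block_dataset(cfg)
        csi = CSIModel(table, compounds, sequences, train_config).fit(seed)
        base = BaselineModel(table, compounds, sequences, train_config).fit(seed)
        gap = cosine_group_gap(csi.compound_embeddings(), cgroups)
        out["csi_ap"].append(csi.test_ap)
        out["baseline_ap"].append(base.test_ap)
        out["cosine_gap"].append(gap)
        out["csi_reports"].append(csi)
        out["baseline_reports"].append(base)
    out["mean_csi_ap"] = float(np.mean(out["csi_ap"]))
    out["mean_baseline_ap"] = float(np.mean(out["baseline_ap"]))
    out["mean_cosine_gap"] = float(np.mean([g["gap"] for g in out["cosine_gap"]]))
    return out


def run_reaction_benchmark(seeds=(0, 1, 2), key_kind: str = "reaction",
                           train_config: TrainConfig | None = None,
                           n_reactions: int = 40) -> dict:
    """Three-view reaction-feature model on the induced interaction table."""
    train_config = train_config or BENCHMARK_CONFIG
    out = {"seeds": list(seeds), "ap": [], "initial_loss": [], "final_loss": []}
    for seed in seeds:
        block = generate_block_dataset(BlockModelConfig(seed=seed))
        records, induced = generate_reaction_dataset(
            ReactionModelConfig(n_reactions=n_reactions, seed=seed), block
        )
        model = ReactionCSIModel(records, induced, block[1], block[2],
                                 train_config, key_kind=key_kind)
        res = model.fit(seed)
        out["ap"].append(res.test_ap)
        out["initial_loss"].append(res.history["phase1_loss"][0])
        out["final_loss"].append(res.history["phase1_loss"][-1])
    out["mean_ap"] = float(np.mean(out["ap"]))
    return out
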