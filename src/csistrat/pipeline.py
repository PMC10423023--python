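"""Two-phase training pipeline.

Phase 1 pretrains view encoders contrastively over strata: each minibatch
draws ``k`` distinct keys and one congruent view tuple per key, so every
other in-batch item is a non-congruent candidate. Phase 2 freezes the
encoders and trains an MLP on concatenated view embeddings of labelled
compound-sequence pairs, with the positive class up-weighted by the
negative:positive ratio. A no-stratification baseline trains the same
encoder architectures end to end, jointly with the MLP, on identical
splits and negative sets.

Inference-time composition of the frozen views for a pair (c, s): the
lone-object encoders are applied directly and each Siamese arm is applied
to the duplicated pair, preserving the dimensions the arms were trained
with; the four (compound-stratification, sequence-stratification) or three
(reaction-feature) view embeddings are concatenated into the MLP input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .contrastive import multiview_loss_t, total_loss_t
from .data import EncodedSequence, InteractionTable, MolecularGraph, encode_sequence, featurize_compound
from .encoders import CNNEncoder, EncoderConfig, GCNEncoder, encode_pairs_t
from .metrics import RankingReport, build_report
from .nn import MLP, Adam, Module, Tensor, concatenate
from .stratify import Stratum

logger = logging.getLogger(__name__)

PHASE1_MODES = ("compound_key", "sequence_key", "reaction_feature")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for both training phases.

    Defaults follow the reference protocol: 700 contrastive epochs, 200
    predictor epochs with early stopping on validation loss, an 8:1:1
    train/validation/test split, temperature 0.07 and a 5:1 train
    negative:positive ratio; the test ratio is configurable (1, 5, 10 or
    25 are the conventional settings).
    """

    phase1_epochs: int = 700
    phase2_epochs: int = 200
    baseline_epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 8
    predictor_batch_size: int = 64
    temperature: float = 0.07
    neg_pos_ratio_train: int = 5
    test_neg_ratio: int = 1
    split_ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    patience: int = 10
    L_max: int = 1000
    mlp_hidden: tuple[int, ...] = (128, 32)
    reaction_views: tuple[int, ...] = (1, 2, 3)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self):
        if any(r <= 0 for r in self.split_ratios) or len(self.split_ratios) != 3:
            raise ValueError("split_ratios must be three positive numbers")
        if min(self.phase1_epochs, self.phase2_epochs, self.baseline_epochs) < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.neg_pos_ratio_train < 1 or self.test_neg_ratio < 1:
            raise ValueError("negative ratios must be >= 1")
        if not set(self.reaction_views) <= {1, 2, 3} or len(self.reaction_views) < 2:
            raise ValueError("reaction_views must be >= 2 of {1, 2, 3}")


class FeatureCache:
    """Lazy featurization of compounds (graphs) and sequences (tokens)."""

    def __init__(self, compounds: dict[str, str], sequences: dict[str, str], L_max: int):
        self.compounds = compounds
        self.sequences = sequences
        self.L_max = L_max
        self._graphs: dict[str, MolecularGraph] = {}
        self._seqs: dict[str, EncodedSequence] = {}

    def graph(self, cid: str) -> MolecularGraph:
        if cid not in self._graphs:
            self._graphs[cid] = featurize_compound(self.compounds[cid])
        return self._graphs[cid]

    def seq(self, sid: str) -> EncodedSequence:
        if sid not in self._seqs:
            self._seqs[sid] = encode_sequence(self.sequences[sid], self.L_max)
        return self._seqs[sid]


# ---------------------------------------------------------------------------
# negative sampling and splits
# ---------------------------------------------------------------------------

def _candidate_pairs(table: InteractionTable, exclude=frozenset()) -> list[tuple[str, str]]:
    blocked = table.positives | table.negatives | frozenset(exclude)
    return [
        (c, s)
        for c in table.compound_ids
        for s in table.sequence_ids
        if (c, s) not in blocked
    ]


def _draw_pairs(candidates, n: int, rng: np.random.Generator) -> set[tuple[str, str]]:
    if n > len(candidates):
        raise ValueError(
            f"cannot sample {n} negatives: only {len(candidates)} candidate "
            f"pairs available (deficit {n - len(candidates)})"
        )
    idx = rng.choice(len(candidates), size=n, replace=False)
    return {candidates[i] for i in idx}


def sample_negatives(table: InteractionTable, ratio: int, seed: int,
                     exclude=frozenset()) -> set[tuple[str, str]]:
    """Draw ratio * |positives| non-positive pairs uniformly without
    replacement from C x S, excluding known positives and labelled
    negatives. Deterministic given the seed."""
    rng = np.random.Generator(np.random.PCG64(seed))
    return _draw_pairs(_candidate_pairs(table, exclude), ratio * len(table.positives), rng)


def make_unseen_split(table: InteractionTable, fraction: float
                      ) -> tuple[InteractionTable, InteractionTable]:
    """Hold out the least-frequent entities for an unseen-generalization set.

    The ``fraction`` of compounds and of sequences with the lowest positive
    interaction counts (ties broken lexicographically by id) are marked
    unseen; every positive touching an unseen entity moves to the unseen
    table, the rest form the train table. The two tables partition the
    positives.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    c_count = {c: 0 for c in table.compound_ids}
    s_count = {s: 0 for s in table.sequence_ids}
    for c, s in table.positives:
        c_count[c] += 1
        s_count[s] += 1
    n_c = int(fraction * len(table.compound_ids))
    n_s = int(fraction * len(table.sequence_ids))
    if n_c >= len(table.compound_ids) or n_s >= len(table.sequence_ids):
        raise ValueError("fraction would remove all entities")
    unseen_c = set(sorted(c_count, key=lambda c: (c_count[c], c))[:n_c])
    unseen_s = set(sorted(s_count, key=lambda s: (s_count[s], s))[:n_s])
    unseen_pos = {
        (c, s) for c, s in table.positives if c in unseen_c or s in unseen_s
    }
    train_pos = table.positives - unseen_pos
    if not train_pos:
        raise ValueError("unseen split would empty the training table")
    # the train table's registries exclude the held-out entities, so negative
    # sampling against it can never touch them either
    train_table = InteractionTable(
        frozenset(train_pos),
        frozenset(p for p in table.negatives
                  if p[0] not in unseen_c and p[1] not in unseen_s),
        tuple(c for c in table.compound_ids if c not in unseen_c),
        tuple(s for s in table.sequence_ids if s not in unseen_s),
    )
    return train_table, table.restrict(unseen_pos)


@dataclass(frozen=True)
class Splits:
    """8:1:1-style split with per-split positive and negative pair sets."""

    train_pos: frozenset
    val_pos: frozenset
    test_pos: frozenset
    train_neg: frozenset
    val_neg: frozenset
    test_neg: frozenset

    def labelled(self, part: str) -> tuple[list[tuple[str, str]], np.ndarray]:
        pos = sorted(getattr(self, f"{part}_pos"))
        neg = sorted(getattr(self, f"{part}_neg"))
        pairs = pos + neg
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        return pairs, labels


def prepare_splits(table: InteractionTable, config: TrainConfig, seed: int) -> Splits:
    """Split positives by ``split_ratios`` and sample split-disjoint negatives.

    Negative pools for train/validation use ``neg_pos_ratio_train``; the
    test pool uses ``test_neg_ratio``. Labelled negatives provided in the
    input table are added to the train pool as-is and never re-sampled.
    Fully deterministic given the master seed.
    """
    ss = np.random.SeedSequence(seed)
    rng_split, rng_tr, rng_va, rng_te = (
        np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4)
    )
    pos = sorted(table.positives)
    rng_split.shuffle(pos)
    ratios = np.asarray(config.split_ratios, dtype=float)
    ratios = ratios / ratios.sum()
    n = len(pos)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    train_pos = frozenset(pos[:n_train])
    val_pos = frozenset(pos[n_train : n_train + n_val])
    test_pos = frozenset(pos[n_train + n_val :])

    taken: set[tuple[str, str]] = set()
    out_negs = []
    for rng, part_pos, ratio in (
        (rng_tr, train_pos, config.neg_pos_ratio_train),
        (rng_va, val_pos, config.neg_pos_ratio_train),
        (rng_te, test_pos, config.test_neg_ratio),
    ):
        cands = _candidate_pairs(table, exclude=taken)
        drawn = _draw_pairs(cands, ratio * len(part_pos), rng)
        taken |= drawn
        out_negs.append(frozenset(drawn))
    train_neg = out_negs[0] | table.negatives
    return Splits(train_pos, val_pos, test_pos, train_neg, out_negs[1], out_negs[2])


# ---------------------------------------------------------------------------
# phase 1: contrastive pretraining
# ---------------------------------------------------------------------------

class ContrastiveEncoders(Module):
    """The frozen product of one phase-1 run (one stratification mode)."""

    def __init__(self, mode: str, modules: dict[str, Module]):
        super().__init__()
        self.mode = mode
        for name, m in modules.items():
            setattr(self, name, m)
        self.module_names = tuple(modules)
        self.frozen = False
        self.epoch_losses: list[float] = []


def _sample_views(stratum: Stratum, rng: np.random.Generator):
    if stratum.kind in ("compound", "sequence"):
        return stratum.views[rng.integers(len(stratum.views))]
    return tuple(vl[rng.integers(len(vl))] for vl in stratum.views)


def _phase1_batches(strata, k, rng):
    order = rng.permutation(len(strata))
    for i in range(0, len(order), k):
        yield [strata[j] for j in order[i : i + k]]


def train_phase1(strata: list[Stratum], mode: str, config: TrainConfig,
                 features: FeatureCache, seed: int = 0) -> ContrastiveEncoders:
    """Contrastively pretrain the encoders of one stratification mode.

    Each epoch visits every key once; batches of ``batch_size`` distinct
    keys contribute the symmetric (or pairwise multiview) contrastive loss.
    Returns the encoders flagged frozen, with the per-epoch loss trace.
    """
    if not strata:
        raise ValueError("no strata to train on")
    if mode not in PHASE1_MODES:
        raise ValueError(f"unknown phase-1 mode {mode!r}")
    ss = np.random.SeedSequence(seed)
    init_rng, batch_rng = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))
    d = config.encoder.embed_dim
    enc_cfg = config.encoder
    if mode == "compound_key":
        mods = {
            "gcn_single": GCNEncoder(2 * d, enc_cfg, init_rng),
            "cnn_arm": CNNEncoder(d, enc_cfg, init_rng),
        }
    elif mode == "sequence_key":
        mods = {
            "gcn_arm": GCNEncoder(d, enc_cfg, init_rng),
            "cnn_single": CNNEncoder(2 * d, enc_cfg, init_rng),
        }
    else:
        mods = {
            "gcn_arm": GCNEncoder(d, enc_cfg, init_rng),
            "gcn_v2": GCNEncoder(d, enc_cfg, init_rng),
            "cnn_v2": CNNEncoder(d, enc_cfg, init_rng),
            "cnn_arm": CNNEncoder(d, enc_cfg, init_rng),
        }
    enc = ContrastiveEncoders(mode, mods)
    opt = Adam(enc.parameters(), lr=config.learning_rate)
    tau = config.temperature
    short_batch_logged = False

    for _epoch in range(config.phase1_epochs):
        losses = []
        for batch in _phase1_batches(strata, config.batch_size, batch_rng):
            k = len(batch)
            if k < config.batch_size and not short_batch_logged:
                logger.warning(
                    "phase 1 batch reduced to %d keys (only %d strata)", k, len(strata)
                )
                short_batch_logged = True
            if k == 1:
                losses.append(0.0)  # single key: loss identically zero
                continue
            views = [_sample_views(s, batch_rng) for s in batch]
            if mode == "compound_key":
                Z1 = mods["gcn_single"].encode([features.graph(v[0]) for v in views])
                Z2 = encode_pairs_t(
                    mods["cnn_arm"],
                    [features.seq(v[1][0]) for v in views],
                    [features.seq(v[1][1]) for v in views],
                )
                loss = total_loss_t(Z1, Z2, tau)
            elif mode == "sequence_key":
                Z1 = encode_pairs_t(
                    mods["gcn_arm"],
                    [features.graph(v[1][0]) for v in views],
                    [features.graph(v[1][1]) for v in views],
                )
                Z2 = mods["cnn_single"].encode([features.seq(v[0]) for v in views])
                loss = total_loss_t(Z1, Z2, tau)
            else:
                batches = []
                if 1 in config.reaction_views:
                    batches.append(encode_pairs_t(
                        mods["gcn_arm"],
                        [features.graph(v[0][0]) for v in views],
                        [features.graph(v[0][1]) for v in views],
                    ))
                if 2 in config.reaction_views:
                    batches.append(concatenate([
                        mods["gcn_v2"].encode([features.graph(v[1][0]) for v in views]),
                        mods["cnn_v2"].encode([features.seq(v[1][1]) for v in views]),
                    ], axis=1))
                if 3 in config.reaction_views:
                    batches.append(encode_pairs_t(
                        mods["cnn_arm"],
                        [features.seq(v[2][0]) for v in views],
                        [features.seq(v[2][1]) for v in views],
                    ))
                loss = multiview_loss_t(batches, tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        enc.epoch_losses.append(float(np.mean(losses)) if losses else 0.0)
    enc.frozen = True
    return enc


# ---------------------------------------------------------------------------
# phase 2: frozen-encoder prediction
# ---------------------------------------------------------------------------

def _embed_entities(encoders: list[ContrastiveEncoders], features: FeatureCache,
                    compound_ids, sequence_ids, chunk: int = 64):
    """Per-entity frozen view embeddings keyed by id."""
    comp_parts: dict[str, list[np.ndarray]] = {c: [] for c in compound_ids}
    seq_parts: dict[str, list[np.ndarray]] = {s: [] for s in sequence_ids}

    def run(encode, items, out, key):
        for i in range(0, len(items), chunk):
            ids = items[i : i + chunk]
            Z = encode(ids).data
            for j, eid in enumerate(ids):
                out[eid].append(Z[j])

    compound_ids = list(compound_ids)
    sequence_ids = list(sequence_ids)
    for enc in encoders:
        if enc.mode == "compound_key":
            run(lambda ids: enc.gcn_single.encode([features.graph(c) for c in ids]),
                compound_ids, comp_parts, "gcn_single")
            # Siamese arm applied to the duplicated pair (s, s)
            run(lambda ids: enc.cnn_arm.encode([features.seq(s) for s in ids]),
                sequence_ids, seq_parts, "cnn_arm")
            for s in sequence_ids:
                seq_parts[s].append(seq_parts[s][-1])
        elif enc.mode == "sequence_key":
            run(lambda ids: enc.gcn_arm.encode([features.graph(c) for c in ids]),
                compound_ids, comp_parts, "gcn_arm")
            for c in compound_ids:
                comp_parts[c].append(comp_parts[c][-1])
            run(lambda ids: enc.cnn_single.encode([features.seq(s) for s in ids]),
                sequence_ids, seq_parts, "cnn_single")
        else:  # reaction_feature
            run(lambda ids: enc.gcn_arm.encode([features.graph(c) for c in ids]),
                compound_ids, comp_parts, "gcn_arm")
            for c in compound_ids:
                comp_parts[c].append(comp_parts[c][-1])
            run(lambda ids: enc.gcn_v2.encode([features.graph(c) for c in ids]),
                compound_ids, comp_parts, "gcn_v2")
            run(lambda ids: enc.cnn_v2.encode([features.seq(s) for s in ids]),
                sequence_ids, seq_parts, "cnn_v2")
            run(lambda ids: enc.cnn_arm.encode([features.seq(s) for s in ids]),
                sequence_ids, seq_parts, "cnn_arm")
            for s in sequence_ids:
                seq_parts[s].append(seq_parts[s][-1])
    comp_emb = {c: np.concatenate(v) for c, v in comp_parts.items()}
    seq_emb = {s: np.concatenate(v) for s, v in seq_parts.items()}
    return comp_emb, seq_emb


def _pair_feature_order(encoders: list[ContrastiveEncoders]) -> str:
    return ",".join(e.mode for e in encoders)


def _pair_matrix(pairs, comp_emb, seq_emb, encoders) -> np.ndarray:
    """Assemble MLP inputs. For the two-phase compound/sequence model the
    order is (z_v1,comp + z_v2,comp) + (z_v1,seq + z_v2,seq); for the
    reaction model the three view embeddings are concatenated."""
    rows = []
    modes = [e.mode for e in encoders]
    for c, s in pairs:
        ce, se = comp_emb[c], seq_emb[s]
        if modes == ["compound_key", "sequence_key"]:
            d2 = ce.shape[0] // 2
            rows.append(np.concatenate([ce[:d2], se[:d2], ce[d2:], se[d2:]]))
        else:
            rows.append(np.concatenate([ce, se]))
    return np.asarray(rows)


@dataclass
class PredictorModel:
    """Frozen encoders + MLP head; the full interaction predictor."""

    encoders: list[ContrastiveEncoders]
    mlp: MLP
    features: FeatureCache
    config: TrainConfig
    comp_emb: dict[str, np.ndarray]
    seq_emb: dict[str, np.ndarray]
    encoder_hash: str = ""
    history: dict = field(default_factory=dict)

    def _pair_features(self, pairs) -> np.ndarray:
        known = all(c in self.comp_emb and s in self.seq_emb for c, s in pairs)
        if known:
            return _pair_matrix(pairs, self.comp_emb, self.seq_emb, self.encoders)
        comp_emb, seq_emb = _embed_entities(
            self.encoders, self.features,
            sorted({c for c, _ in pairs}), sorted({s for _, s in pairs}),
        )
        comp_emb = {**comp_emb, **self.comp_emb}
        seq_emb = {**seq_emb, **self.seq_emb}
        return _pair_matrix(pairs, comp_emb, seq_emb, self.encoders)

    def predict_pairs(self, pairs) -> np.ndarray:
        return _mlp_proba(self.mlp, self._pair_features(pairs))

    def predict(self, compound_id: str, sequence_id: str) -> float:
        return float(self.predict_pairs([(compound_id, sequence_id)])[0])


def _mlp_proba(mlp: MLP, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
    out = []
    for i in range(0, len(X), chunk):
        logits = mlp(Tensor(X[i : i + chunk])).data[:, 0]
        out.append(1.0 / (1.0 + np.exp(-logits)))
    return np.concatenate(out) if out else np.zeros(0)


def weighted_bce_t(logits: Tensor, labels: np.ndarray, pos_weight: float) -> Tensor:
    """Mean over examples of w_i * [softplus(x_i) - y_i * x_i], with
    w_i = pos_weight for positives and 1 for negatives."""
    y = np.asarray(labels, dtype=float)
    w = np.where(y == 1, pos_weight, 1.0)
    per = logits.softplus() - logits * Tensor(y)
    return (per * Tensor(w)).mean()


def _val_loss(mlp, X, y, pos_weight) -> float:
    logits = mlp(Tensor(X)).reshape(-1)
    return float(weighted_bce_t(logits, y, pos_weight).data)


def train_phase2(encoders: list[ContrastiveEncoders], splits: Splits,
                 features: FeatureCache, config: TrainConfig, seed: int = 0
                 ) -> PredictorModel:
    """Train the frozen-encoder MLP predictor with early stopping.

    The positive class is weighted by the train negative:positive ratio;
    encoder parameters are verified bit-identical before and after by
    hash.
    """
    for enc in encoders:
        if not getattr(enc, "frozen", False):
            raise ValueError("phase 2 requires frozen phase-1 encoders")
    pre_hashes = [enc.weight_hash() for enc in encoders]
    ss = np.random.SeedSequence(seed)
    init_rng, batch_rng = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))

    all_pairs = set()
    for part in ("train", "val", "test"):
        p, _ = splits.labelled(part)
        all_pairs.update(p)
    comp_ids = sorted({c for c, _ in all_pairs})
    seq_ids = sorted({s for _, s in all_pairs})
    comp_emb, seq_emb = _embed_entities(encoders, features, comp_ids, seq_ids)

    Xy = {}
    for part in ("train", "val", "test"):
        pairs, labels = splits.labelled(part)
        Xy[part] = (pairs, _pair_matrix(pairs, comp_emb, seq_emb, encoders), labels)
    feat_dim = Xy["train"][1].shape[1]
    mlp = MLP([feat_dim] + list(config.mlp_hidden) + [1], init_rng)
    opt = Adam(mlp.parameters(), lr=config.learning_rate)
    n_pos = max(1, len(splits.train_pos))
    pos_weight = len(splits.train_neg) / n_pos

    X_train, y_train = Xy["train"][1], Xy["train"][2]
    X_val, y_val = Xy["val"][1], Xy["val"][2]
    best = (np.inf, None, -1)
    train_losses, val_losses = [], []
    for epoch in range(config.phase2_epochs):
        order = batch_rng.permutation(len(X_train))
        ep = []
        for i in range(0, len(order), config.predictor_batch_size):
            idx = order[i : i + config.predictor_batch_size]
            logits = mlp(Tensor(X_train[idx])).reshape(-1)
            loss = weighted_bce_t(logits, y_train[idx], pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        train_losses.append(float(np.mean(ep)))
        vl = _val_loss(mlp, X_val, y_val, pos_weight)
        val_losses.append(vl)
        if vl < best[0]:
            best = (vl, mlp.state_dict(), epoch)
        elif epoch - best[2] >= config.patience:
            break
    if best[1] is not None:
        mlp.load_state_dict(best[1])

    post_hashes = [enc.weight_hash() for enc in encoders]
    if pre_hashes != post_hashes:
        raise RuntimeError("encoder weights changed during phase 2")
    return PredictorModel(
        encoders=encoders, mlp=mlp, features=features, config=config,
        comp_emb=comp_emb, seq_emb=seq_emb, encoder_hash="|".join(post_hashes),
        history={"train_loss": train_losses, "val_loss": val_losses,
                 "best_epoch": best[2]},
    )


def predict(model: PredictorModel, compound_id: str, sequence_id: str) -> float:
    """Interaction probability for one pair through the frozen views."""
    return model.predict(compound_id, sequence_id)


def evaluate(model: PredictorModel, splits: Splits, part: str = "test",
             k_cut: int = 3) -> RankingReport:
    pairs, labels = splits.labelled(part)
    scores = model.predict_pairs(pairs)
    return build_report(pairs, labels, scores, k_cut=k_cut)


# ---------------------------------------------------------------------------
# no-stratification baseline (joint end-to-end training)
# ---------------------------------------------------------------------------

class BaselinePredictor(Module):
    """GCN + CNN encoders concatenated into an MLP, trained end to end."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        super().__init__()
        d = config.encoder.embed_dim
        self.gcn = GCNEncoder(2 * d, config.encoder, rng)
        self.cnn = CNNEncoder(2 * d, config.encoder, rng)
        self.mlp = MLP([4 * d] + list(config.mlp_hidden) + [1], rng)
        self.config = config

    def logits(self, graphs, seqs) -> Tensor:
        zc = self.gcn.encode(graphs)
        zs = self.cnn.encode(seqs)
        return self.mlp(concatenate([zc, zs], axis=1)).reshape(-1)

    def logits_pairs(self, pairs, features: FeatureCache, chunk: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(pairs), chunk):
            part = pairs[i : i + chunk]
            out.append(self.logits(
                [features.graph(c) for c, _ in part],
                [features.seq(s) for _, s in part],
            ).data)
        return np.concatenate(out)

    def predict_pairs(self, pairs, features: FeatureCache, chunk: int = 256) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits_pairs(pairs, features, chunk)))


def train_baseline(splits: Splits, features: FeatureCache, config: TrainConfig,
                   seed: int = 0) -> BaselinePredictor:
    """Train the no-stratification baseline on the same splits/negatives."""
    ss = np.random.SeedSequence(seed)
    init_rng, batch_rng = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))
    model = BaselinePredictor(config, init_rng)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n_pos = max(1, len(splits.train_pos))
    pos_weight = len(splits.train_neg) / n_pos

    train_pairs, y_train = splits.labelled("train")
    val_pairs, y_val = splits.labelled("val")
    best = (np.inf, None, -1)
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.baseline_epochs):
        order = batch_rng.permutation(len(train_pairs))
        ep = []
        for i in range(0, len(order), config.predictor_batch_size):
            idx = order[i : i + config.predictor_batch_size]
            part = [train_pairs[j] for j in idx]
            logits = model.logits(
                [features.graph(c) for c, _ in part],
                [features.seq(s) for _, s in part],
            )
            loss = weighted_bce_t(logits, y_train[idx], pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        history["train_loss"].append(float(np.mean(ep)))
        logit_v = model.logits_pairs(val_pairs, features)
        vl = float(weighted_bce_t(Tensor(logit_v), y_val, pos_weight).data)
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, model.state_dict(), epoch)
        elif epoch - best[2] >= config.patience:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.history = history
    return model


def evaluate_baseline(model: BaselinePredictor, splits: Splits,
                      features: FeatureCache, k_cut: int = 3) -> RankingReport:
    pairs, labels = splits.labelled("test")
    scores = model.predict_pairs(pairs, features)
    return build_report(pairs, labels, scores, k_cut=k_cut)
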