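"""Model-level API: build a model from data, ``fit`` it, inspect Results.

Three fitted objects are available:

* :class:`CSIModel` — the full stratified pipeline: compound-key and
  sequence-key contrastive pretraining, then a frozen-encoder MLP
  predictor (either stratification can be switched off for ablations);
* :class:`BaselineModel` — the same encoder architectures trained end to
  end jointly with the MLP, with no stratification or contrastive phase,
  on identical splits and negative sets for a given seed;
* :class:`ReactionCSIModel` — stratification by a reaction feature
  (reaction / RCLASS / EC) with the pairwise three-view contrastive loss,
  applied to the interaction table induced by the reactions.

``fit(seed)`` is fully deterministic on a single CPU thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import InteractionTable, ReactionRecord, read_compounds, read_interactions, read_sequences
from .metrics import RankingReport
from .pipeline import (
    BaselinePredictor,
    FeatureCache,
    PredictorModel,
    Splits,
    TrainConfig,
    evaluate,
    evaluate_baseline,
    prepare_splits,
    train_baseline,
    train_phase1,
    train_phase2,
)
from .stratify import stratify_by_compound, stratify_by_reaction_feature, stratify_by_sequence


def _validate_registries(table: InteractionTable, compounds: dict, sequences: dict):
    missing_c = set(table.compound_ids) - set(compounds)
    missing_s = set(table.sequence_ids) - set(sequences)
    if missing_c or missing_s:
        raise ValueError(
            f"unresolved ids: {sorted(missing_c)[:3]} compounds, "
            f"{sorted(missing_s)[:3]} sequences"
        )


@dataclass
class FitResults:
    """Common results surface: report, predictor, training history."""

    report: RankingReport
    splits: Splits
    config: TrainConfig
    seed: int
    model_name: str = "model"
    history: dict = field(default_factory=dict)

    @property
    def test_ap(self) -> float:
        return self.report.overall["AP"]

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit summary (seed {self.seed})",
            "=" * 48,
            f"train/val/test positives: {len(self.splits.train_pos)}/"
            f"{len(self.splits.val_pos)}/{len(self.splits.test_pos)}",
            f"train negatives: {len(self.splits.train_neg)} "
            f"(ratio {self.config.neg_pos_ratio_train}:1); "
            f"test ratio {self.config.test_neg_ratio}:1",
        ]
        for key, val in self.history.items():
            if isinstance(val, list) and val:
                lines.append(f"{key}: first {val[0]:.4f} -> last {val[-1]:.4f}")
            elif np.isscalar(val):
                lines.append(f"{key}: {val}")
        lines.append("-" * 48)
        lines.append(self.report.to_tsv().rstrip())
        return "\n".join(lines)


@dataclass
class CSIResults(FitResults):
    predictor: PredictorModel | None = None

    def predict(self, compound_id: str, sequence_id: str) -> float:
        return self.predictor.predict(compound_id, sequence_id)

    def compound_embeddings(self) -> dict[str, np.ndarray]:
        """Frozen compound-view embeddings from the compound-key phase."""
        for enc in self.predictor.encoders:
            if enc.mode == "compound_key":
                ids = sorted(self.predictor.features.compounds)
                feats = self.predictor.features
                out = {}
                for i in range(0, len(ids), 64):
                    chunk = ids[i : i + 64]
                    Z = enc.gcn_single.encode([feats.graph(c) for c in chunk]).data
                    out.update(dict(zip(chunk, Z)))
                return out
        raise ValueError("no compound-key phase in this fit")


@dataclass
class BaselineResults(FitResults):
    predictor: BaselinePredictor | None = None
    features: FeatureCache | None = None

    def predict(self, compound_id: str, sequence_id: str) -> float:
        return float(
            self.predictor.predict_pairs([(compound_id, sequence_id)], self.features)[0]
        )


class _ModelBase:
    def __init__(self, table: InteractionTable, compounds: dict[str, str],
                 sequences: dict[str, str], config: TrainConfig | None = None):
        config = config or TrainConfig()
        _validate_registries(table, compounds, sequences)
        self.table = table
        self.compounds = compounds
        self.sequences = sequences
        self.config = config
        self.features = FeatureCache(compounds, sequences, config.L_max)

    @classmethod
    def from_files(cls, interactions_path, compounds_path, sequences_path,
                   config: TrainConfig | None = None):
        return cls(
            read_interactions(interactions_path),
            read_compounds(compounds_path),
            read_sequences(sequences_path),
            config,
        )


class CSIModel(_ModelBase):
    """Contrastive-stratification interaction model.

    Parameters
    ----------
    table, compounds, sequences
        Interaction table plus id -> SMILES and id -> residue-string maps.
    config
        :class:`TrainConfig`; defaults follow the reference protocol.
    stratifications
        Which key kinds to pretrain on; default both ``("compound",
        "sequence")``. A single kind reproduces the ablation variants.
    """

    def __init__(self, table, compounds, sequences, config=None,
                 stratifications: tuple[str, ...] = ("compound", "sequence")):
        super().__init__(table, compounds, sequences, config)
        if not stratifications or not set(stratifications) <= {"compound", "sequence"}:
            raise ValueError("stratifications must be a subset of {'compound','sequence'}")
        self.stratifications = tuple(stratifications)

    def fit(self, seed: int = 0) -> CSIResults:
        ss = np.random.SeedSequence(seed)
        s_split, s_p1a, s_p1b, s_p2 = (int(c.generate_state(1)[0] % 2**31)
                                       for c in ss.spawn(4))
        splits = prepare_splits(self.table, self.config, s_split)
        train_table = self.table.restrict(splits.train_pos)
        encoders = []
        history = {}
        if "compound" in self.stratifications:
            strata = stratify_by_compound(train_table)
            enc = train_phase1(strata, "compound_key", self.config, self.features, s_p1a)
            encoders.append(enc)
            history["phase1A_loss"] = enc.epoch_losses
        if "sequence" in self.stratifications:
            strata = stratify_by_sequence(train_table)
            enc = train_phase1(strata, "sequence_key", self.config, self.features, s_p1b)
            encoders.append(enc)
            history["phase1B_loss"] = enc.epoch_losses
        predictor = train_phase2(encoders, splits, self.features, self.config, s_p2)
        history.update({f"phase2_{k}": v for k, v in predictor.history.items()})
        report = evaluate(predictor, splits)
        return CSIResults(
            report=report, splits=splits, config=self.config, seed=seed,
            model_name="CSI (" + "+".join(self.stratifications) + " stratification)",
            history=history, predictor=predictor,
        )


class BaselineModel(_ModelBase):
    """No-stratification baseline: joint end-to-end GCN + CNN + MLP."""

    def fit(self, seed: int = 0) -> BaselineResults:
        ss = np.random.SeedSequence(seed)
        s_split, _, _, s_train = (int(c.generate_state(1)[0] % 2**31)
                                  for c in ss.spawn(4))
        splits = prepare_splits(self.table, self.config, s_split)
        predictor = train_baseline(splits, self.features, self.config, s_train)
        report = evaluate_baseline(predictor, splits, self.features)
        return BaselineResults(
            report=report, splits=splits, config=self.config, seed=seed,
            model_name="baseline (no stratification)",
            history=predictor.history, predictor=predictor, features=self.features,
        )


class ReactionCSIModel(_ModelBase):
    """Reaction-feature stratification with the three-view contrastive loss.

    The interaction table is induced from the reactions (compound-enzyme
    pairs); ``key_kind`` picks the stratification key among ``"reaction"``,
    ``"rclass"`` and ``"ec"``; ``config.reaction_views`` selects the view
    subset for ablations.
    """

    def __init__(self, reactions: list[ReactionRecord], table: InteractionTable,
                 compounds, sequences, config=None, key_kind: str = "reaction"):
        super().__init__(table, compounds, sequences, config)
        self.reactions = reactions
        self.key_kind = key_kind

    def fit(self, seed: int = 0) -> CSIResults:
        ss = np.random.SeedSequence(seed)
        s_split, s_p1, s_p2 = (int(c.generate_state(1)[0] % 2**31)
                               for c in ss.spawn(3))
        splits = prepare_splits(self.table, self.config, s_split)
        # pretraining must not see held-out interaction pairs: of the three
        # views only the compound-sequence list (view 2) holds such pairs, so
        # those tuples are trimmed to the train split; reactant-product and
        # enzyme-pair views carry no interaction labels and are kept whole
        held = splits.val_pos | splits.test_pos
        strata = []
        for st in stratify_by_reaction_feature(self.reactions, self.key_kind):
            v1, v2, v3 = st.views
            v2 = tuple(p for p in v2 if p not in held)
            if v1 and v2 and v3:
                strata.append(
                    type(st)(st.kind, st.key_value, (v1, v2, v3), st.members)
                )
        if not strata:
            raise ValueError(
                "no stratum retains a train-split compound-sequence view; "
                "use more reactions or a larger train fraction"
            )
        enc = train_phase1(strata, "reaction_feature", self.config, self.features, s_p1)
        predictor = train_phase2([enc], splits, self.features, self.config, s_p2)
        history = {"phase1_loss": enc.epoch_losses}
        history.update({f"phase2_{k}": v for k, v in predictor.history.items()})
        report = evaluate(predictor, splits)
        return CSIResults(
            report=report, splits=splits, config=self.config, seed=seed,
            model_name=f"CSI ({self.key_kind}-feature stratification, "
                       f"views {self.config.reaction_views})",
            history=history, predictor=predictor,
        )
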