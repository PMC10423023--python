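"""Block-model generator: statistics, determinism, downstream validity."""

import numpy as np
import pytest

import csistrat as cs


def test_positive_count_within_binomial_band():
    cfg = cs.BlockModelConfig(seed=0)
    table, _, _, (cg, sg) = cs.generate_block_dataset(cfg)
    cga = np.array([cg[c] for c in sorted(cg)])
    sga = np.array([sg[s] for s in sorted(sg)])
    same = (cga[:, None] == sga[None, :])
    n_in, n_out = same.sum(), (~same).sum()
    mean = n_in * cfg.p_in + n_out * cfg.p_out
    var = n_in * cfg.p_in * (1 - cfg.p_in) + n_out * cfg.p_out * (1 - cfg.p_out)
    assert abs(table.n_positives - mean) < 4 * np.sqrt(var)


def test_null_construction_no_group_effect():
    """With p_in == p_out (+eps) the within/between rates are indistinguishable."""
    diffs = []
    for seed in range(20):
        cfg = cs.BlockModelConfig(p_in=0.1 + 1e-9, p_out=0.1, seed=seed,
                                  n_compounds=40, n_sequences=40)
        table, _, _, (cg, sg) = cs.generate_block_dataset(cfg)
        within = between = n_w = n_b = 0
        for c in table.compound_ids:
            for s in table.sequence_ids:
                hit = (c, s) in table.positives
                if cg[c] == sg[s]:
                    within += hit
                    n_w += 1
                else:
                    between += hit
                    n_b += 1
        diffs.append(within / n_w - between / n_b)
    # mean difference within ~3 standard errors of zero
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * se + 1e-9


def test_same_seed_byte_identical():
    a = cs.generate_block_dataset(cs.BlockModelConfig(seed=7))
    b = cs.generate_block_dataset(cs.BlockModelConfig(seed=7))
    assert a[0].positives == b[0].positives
    assert a[1] == b[1] and a[2] == b[2] and a[3] == b[3]
    c = cs.generate_block_dataset(cs.BlockModelConfig(seed=8))
    assert c[0].positives != a[0].positives


def test_outputs_featurizable():
    table, compounds, sequences, _ = cs.generate_block_dataset(
        cs.BlockModelConfig(n_compounds=40, n_sequences=40, seed=3)
    )
    for smi in compounds.values():
        assert cs.featurize_compound(smi).n_nodes >= 2
    for seq in sequences.values():
        assert cs.encode_sequence(seq, 128).original_length >= 10


def test_rates_converge_at_large_n():
    cfg = cs.BlockModelConfig(n_compounds=500, n_sequences=500, seed=1,
                              motif_strength=0.0)
    table, _, _, (cg, sg) = cs.generate_block_dataset(cfg)
    cga = np.array([cg[c] for c in table.compound_ids])
    sga = np.array([sg[s] for s in table.sequence_ids])
    hit = np.zeros((500, 500), dtype=bool)
    ci = {c: i for i, c in enumerate(table.compound_ids)}
    si = {s: j for j, s in enumerate(table.sequence_ids)}
    for c, s in table.positives:
        hit[ci[c], si[s]] = True
    same = cga[:, None] == sga[None, :]
    for rate, p, n in ((hit[same].mean(), cfg.p_in, same.sum()),
                       (hit[~same].mean(), cfg.p_out, (~same).sum())):
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 3 * sigma


def test_strata_non_degenerate_under_default_config():
    table, _, _, _ = cs.generate_block_dataset(cs.BlockModelConfig(seed=0))
    partners = {}
    for c, s in table.positives:
        partners.setdefault(c, set()).add(s)
    frac = np.mean([len(partners.get(c, ())) >= 2 for c in table.compound_ids])
    assert frac >= 0.8


def test_oracle_interaction_probability():
    cfg = cs.BlockModelConfig()
    assert cs.oracle_interaction_probability(cfg, 1, 1) == cfg.p_in
    assert cs.oracle_interaction_probability(cfg, 1, 2) == cfg.p_out
    with pytest.raises(ValueError):
        cs.oracle_interaction_probability(cfg, 0, 99)


def test_config_invariants():
    with pytest.raises(ValueError):
        cs.BlockModelConfig(p_in=0.1, p_out=0.2)
    with pytest.raises(ValueError):
        cs.BlockModelConfig(n_groups=100, n_compounds=10, n_sequences=10)


class TestReactionGenerator:
    def test_induced_pairs_enumeration(self):
        block = cs.generate_block_dataset(cs.BlockModelConfig(n_compounds=20,
                                                              n_sequences=20, seed=0))
        cfg = cs.ReactionModelConfig(n_reactions=1, n_reactants=(1, 1),
                                     n_products=(1, 1), n_enzymes=(2, 2),
                                     n_rclasses=1, n_ec_numbers=1, seed=0)
        records, induced = cs.generate_reaction_dataset(cfg, block)
        (rec,) = records
        assert len(rec.enzyme_ids) == 2
        assert induced.n_positives == 4  # 2 compounds x 2 enzymes

    def test_rclass_per_reaction_when_counts_match(self):
        block = cs.generate_block_dataset(cs.BlockModelConfig(seed=0))
        cfg = cs.ReactionModelConfig(n_reactions=12, n_rclasses=12, n_ec_numbers=4, seed=0)
        records, _ = cs.generate_reaction_dataset(cfg, block)
        strata = cs.stratify_by_reaction_feature(records, "reaction")
        assert len(strata) == 12

    def test_same_seed_identical_and_groups_coherent(self):
        block = cs.generate_block_dataset(cs.BlockModelConfig(seed=2))
        cfg = cs.ReactionModelConfig(seed=5)
        a, _ = cs.generate_reaction_dataset(cfg, block)
        b, _ = cs.generate_reaction_dataset(cfg, block)
        assert a == b
        cg, sg = block[3]
        for rec in a:
            groups = {cg[c] for c in rec.reactant_ids + rec.product_ids}
            groups |= {sg[e] for e in rec.enzyme_ids}
            assert len(groups) == 1  # all drawn from one latent group

    def test_group_too_small_raises(self):
        block = cs.generate_block_dataset(
            cs.BlockModelConfig(n_compounds=4, n_sequences=4, n_groups=4, seed=0)
        )
        cfg = cs.ReactionModelConfig(n_reactions=2, n_reactants=(3, 3),
                                     n_products=(3, 3), n_rclasses=2, n_ec_numbers=2)
        with pytest.raises(ValueError):
            cs.generate_reaction_dataset(cfg, block)
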