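import numpy as np
import pytest

import csistrat as cs
from csistrat.pipeline import TrainConfig


@pytest.fixture
def tiny_table():
    """Four positives over 2 compounds x 3 sequences."""
    return cs.InteractionTable(
        frozenset({("c1", "s1"), ("c1", "s2"), ("c1", "s3"), ("c2", "s1")})
    )


@pytest.fixture(scope="session")
def small_block():
    """30x30 block dataset shared by the fast pipeline tests."""
    cfg = cs.BlockModelConfig(n_compounds=30, n_sequences=30, seed=0)
    return cs.generate_block_dataset(cfg), cfg


@pytest.fixture(scope="session")
def fast_config():
    return TrainConfig(phase1_epochs=4, phase2_epochs=5, baseline_epochs=3, L_max=64)


def random_table(rng: np.random.Generator, n_c=6, n_s=6, p=0.4) -> cs.InteractionTable:
    comps = [f"c{i}" for i in range(n_c)]
    seqs = [f"s{j}" for j in range(n_s)]
    pos = {
        (c, s) for c in comps for s in seqs if rng.random() < p
    }
    if not pos:
        pos = {(comps[0], seqs[0])}
    return cs.InteractionTable(frozenset(pos), frozenset(), tuple(comps), tuple(seqs))
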