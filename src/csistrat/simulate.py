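"""Self-contained synthetic benchmark data.

The generator emulates the statistical structure a stratification-based
contrastive learner exploits in real compound-protein data: a bipartite
block model in which compounds and protein sequences each belong to one of
G latent groups, same-group pairs interact with probability ``p_in`` and
cross-group pairs with ``p_out`` << ``p_in``, and group identity is
detectable from the raw inputs because each group carries a chemical motif
(a functional-group substructure appended to a random alkane/ether
backbone) and a sequence motif (a fixed 6-mer inserted at a random
position), each present with probability ``motif_strength``.

A companion reaction generator emits reaction records whose reactants,
products and enzymes are drawn from matched groups, with RCLASS/EC labels
allocated so that reactions sharing a label share a group; the induced
compound-enzyme pairs form the interaction table for downstream
prediction.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` children, so every artefact is byte-stable
for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AA_ALPHABET, InteractionTable, ReactionRecord

# group motif vocabularies; groups cycle through them
COMPOUND_MOTIFS = [
    "C(=O)O",        # carboxylic acid
    "S(=O)(=O)N",    # sulfonamide
    "C(F)(F)F",      # trifluoromethyl
    "N(C)C",         # dimethylamino
    "C(=O)N",        # amide
    "C#N",           # nitrile
    "OCC(=O)O",      # glycolic tail
    "C(Cl)Cl",       # dichloromethyl
]
_MOTIF_HEAVY_ATOMS = [3, 4, 4, 3, 3, 2, 5, 3]

SEQUENCE_MOTIFS = [
    "WHWKFY", "DEDERD", "KRKRHK", "FYWFMW",
    "PGPGSG", "CMCTAC", "ILVLIV", "QNQEQN",
]


@dataclass(frozen=True)
class BlockModelConfig:
    n_compounds: int = 80
    n_sequences: int = 80
    n_groups: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    motif_strength: float = 0.9
    seq_length: tuple[int, int] = (50, 120)
    mol_size: tuple[int, int] = (8, 20)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_groups > min(self.n_compounds, self.n_sequences):
            raise ValueError("more groups than entities")
        if min(self.n_compounds, self.n_sequences, self.n_groups) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.motif_strength <= 1):
            raise ValueError("motif_strength must be in [0, 1]")
        if self.seq_length[0] < 10 or self.seq_length[0] > self.seq_length[1]:
            raise ValueError("bad seq_length range")
        if self.mol_size[0] < 4 or self.mol_size[0] > self.mol_size[1]:
            raise ValueError("bad mol_size range")


@dataclass(frozen=True)
class ReactionModelConfig:
    n_reactions: int = 40
    n_reactants: tuple[int, int] = (1, 2)
    n_products: tuple[int, int] = (1, 2)
    n_enzymes: tuple[int, int] = (1, 3)
    n_rclasses: int = 8
    n_ec_numbers: int = 8
    seed: int = 0

    def __post_init__(self):
        for rng_field in (self.n_reactants, self.n_products, self.n_enzymes):
            if rng_field[0] < 1 or rng_field[0] > rng_field[1]:
                raise ValueError("reaction size ranges must be >= 1 and ordered")
        if not (1 <= self.n_rclasses <= self.n_reactions):
            raise ValueError("n_rclasses must be in [1, n_reactions]")
        if not (1 <= self.n_ec_numbers <= self.n_reactions):
            raise ValueError("n_ec_numbers must be in [1, n_reactions]")


def _assign_groups(n: int, G: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform assignment with every group guaranteed non-empty."""
    groups = rng.integers(0, G, size=n)
    head = rng.permutation(n)[:G]
    groups[head] = np.arange(G)
    return groups


def _random_backbone(n_atoms: int, rng: np.random.Generator) -> str:
    """Linear alkane/ether chain of n_atoms heavy atoms (no adjacent O)."""
    atoms = []
    prev_o = True  # avoid starting with O
    for _ in range(n_atoms):
        if not prev_o and rng.random() < 0.2:
            atoms.append("O")
            prev_o = True
        else:
            atoms.append("C")
            prev_o = False
    return "".join(atoms)


def _random_smiles(group: int, config: BlockModelConfig, rng: np.random.Generator) -> str:
    lo, hi = config.mol_size
    n_target = int(rng.integers(lo, hi + 1))
    motif_idx = group % len(COMPOUND_MOTIFS)
    with_motif = rng.random() < config.motif_strength
    n_motif = _MOTIF_HEAVY_ATOMS[motif_idx] if with_motif else 0
    backbone = _random_backbone(max(2, n_target - n_motif), rng)
    return backbone + (COMPOUND_MOTIFS[motif_idx] if with_motif else "")


def _random_sequence(group: int, config: BlockModelConfig, rng: np.random.Generator) -> str:
    lo, hi = config.seq_length
    L = int(rng.integers(lo, hi + 1))
    seq = list(rng.choice(list(AA_ALPHABET), size=L))
    if rng.random() < config.motif_strength:
        motif = SEQUENCE_MOTIFS[group % len(SEQUENCE_MOTIFS)]
        pos = int(rng.integers(0, L - len(motif) + 1))
        seq[pos : pos + len(motif)] = list(motif)
    return "".join(seq)


def generate_block_dataset(config: BlockModelConfig):
    """Build the block-model benchmark dataset.

    Returns ``(table, compounds, sequences, groups)`` where ``compounds``
    maps compound id -> SMILES, ``sequences`` maps sequence id -> residue
    string and ``groups`` is ``(compound_groups, sequence_groups)`` as
    id -> group-index dicts.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_groups, rng_inter, rng_mol, rng_seq = (
        np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(4)
    )
    nc, ns, G = config.n_compounds, config.n_sequences, config.n_groups
    comp_ids = [f"C{i:04d}" for i in range(nc)]
    seq_ids = [f"S{i:04d}" for i in range(ns)]
    cg = _assign_groups(nc, G, rng_groups)
    sg = _assign_groups(ns, G, rng_groups)

    P = np.where(cg[:, None] == sg[None, :], config.p_in, config.p_out)
    hits = rng_inter.random((nc, ns)) < P
    positives = frozenset(
        (comp_ids[i], seq_ids[j]) for i, j in zip(*np.nonzero(hits))
    )
    table = InteractionTable(positives, frozenset(), tuple(comp_ids), tuple(seq_ids))

    compounds = {cid: _random_smiles(cg[i], config, rng_mol) for i, cid in enumerate(comp_ids)}
    sequences = {sid: _random_sequence(sg[j], config, rng_seq) for j, sid in enumerate(seq_ids)}
    groups = (
        {cid: int(cg[i]) for i, cid in enumerate(comp_ids)},
        {sid: int(sg[j]) for j, sid in enumerate(seq_ids)},
    )
    return table, compounds, sequences, groups


def oracle_interaction_probability(config: BlockModelConfig, group_c: int, group_s: int) -> float:
    """Ground-truth interaction probability for a pair of group indices."""
    for g in (group_c, group_s):
        if not (0 <= g < config.n_groups):
            raise ValueError(f"group index {g} out of range")
    return config.p_in if group_c == group_s else config.p_out


def generate_reaction_dataset(config: ReactionModelConfig, block):
    """Reactions drawn group-coherently from a block dataset.

    ``block`` is the tuple returned by :func:`generate_block_dataset`.
    Returns ``(records, induced_table)`` where the induced table holds the
    compound-enzyme pairs implied by each reaction (compound in R or P,
    enzyme catalyzing it).
    """
    table, compounds, sequences, (comp_groups, seq_groups) = block
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    G = max(comp_groups.values()) + 1
    comps_by_group = [sorted(c for c, g in comp_groups.items() if g == grp) for grp in range(G)]
    seqs_by_group = [sorted(s for s, g in seq_groups.items() if g == grp) for grp in range(G)]

    # label spaces partitioned by group so same-label reactions share a group
    rclass_group = [i % G for i in range(config.n_rclasses)]
    ec_group = [i % G for i in range(config.n_ec_numbers)]

    records = []
    induced: set[tuple[str, str]] = set()
    for i in range(config.n_reactions):
        grp = i % G
        n_r = int(rng.integers(config.n_reactants[0], config.n_reactants[1] + 1))
        n_p = int(rng.integers(config.n_products[0], config.n_products[1] + 1))
        n_e = int(rng.integers(config.n_enzymes[0], config.n_enzymes[1] + 1))
        if n_r + n_p > len(comps_by_group[grp]) or n_e > len(seqs_by_group[grp]):
            raise ValueError(
                f"group {grp} too small for a reaction of size "
                f"{n_r}+{n_p} compounds / {n_e} enzymes"
            )
        picked = rng.choice(comps_by_group[grp], size=n_r + n_p, replace=False)
        enzymes = rng.choice(seqs_by_group[grp], size=n_e, replace=False)
        rc_candidates = [j for j in range(config.n_rclasses) if rclass_group[j] == grp]
        ec_candidates = [j for j in range(config.n_ec_numbers) if ec_group[j] == grp]
        rc = int(rng.choice(rc_candidates)) if rc_candidates else grp % config.n_rclasses
        ec = int(rng.choice(ec_candidates)) if ec_candidates else grp % config.n_ec_numbers
        rec = ReactionRecord(
            reaction_id=f"R{i:04d}",
            reactant_ids=tuple(str(x) for x in picked[:n_r]),
            product_ids=tuple(str(x) for x in picked[n_r:]),
            enzyme_ids=tuple(sorted(str(x) for x in enzymes)),
            rclass_id=f"RC{rc:03d}",
            ec_number=f"{grp + 1}.1.1.{ec + 1}",
        )
        records.append(rec)
        for c in rec.reactant_ids + rec.product_ids:
            for e in rec.enzyme_ids:
                induced.add((c, e))
    induced_table = InteractionTable(
        frozenset(induced), frozenset(), table.compound_ids, table.sequence_ids
    )
    return records, induced_table
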