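"""Core data types and I/O for compound-protein interaction datasets.

The package works from four plain-text inputs:

* an interaction table (TSV: ``compound_id``, ``sequence_id``, optional
  binary ``label``) holding known positive pairs and, optionally, labelled
  negatives (e.g. inhibitors);
* compound structures as a TSV of ``compound_id`` -> SMILES;
* protein sequences as FASTA (record id = sequence id);
* a reaction table (TSV: ``reaction_id``, ``reactants``, ``products``,
  ``enzymes``, ``rclass``, ``ec``; multi-valued fields joined with ``|``).

Compounds are featurized into heavy-atom molecular graphs with rdkit;
protein sequences are tokenized over the 20 standard residues plus a single
unknown symbol and padded/truncated to a fixed length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

MULTI_VALUE_DELIMITER = "|"

# 20 standard residues; token 0 is padding, 1..20 the residues, 21 unknown.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_TOKEN = len(AA_ALPHABET) + 1
ALPHABET_SIZE = len(AA_ALPHABET) + 1  # content tokens (residues + unknown)
_AA_INDEX = {aa: i + 1 for i, aa in enumerate(AA_ALPHABET)}

ATOM_VOCAB = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]  # + "other" bucket
NODE_FEATURE_DIM = len(ATOM_VOCAB) + 1 + 9
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
N_STEREO = 6
EDGE_FEATURE_DIM = len(BOND_TYPES) + 2 + N_STEREO


class FormatError(ValueError):
    """Malformed input file (missing column, empty mandatory field...)."""


class PairConflictError(FormatError):
    """The same compound-sequence pair appears with both labels."""


class SMILESParseError(ValueError):
    """SMILES string that rdkit cannot parse."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class InteractionTable:
    """The interaction set I over compounds C and sequences S.

    ``positives`` holds known interacting pairs, ``negatives`` optional
    labelled non-interacting pairs. Id registries preserve a stable order.
    """

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]] = frozenset()
    compound_ids: tuple[str, ...] = ()
    sequence_ids: tuple[str, ...] = ()

    def __post_init__(self):
        pos = frozenset(self.positives)
        neg = frozenset(self.negatives)
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)
        overlap = pos & neg
        if overlap:
            raise PairConflictError(
                f"pairs labelled both positive and negative: {sorted(overlap)[:5]}"
            )
        if not self.compound_ids:
            object.__setattr__(
                self, "compound_ids", tuple(sorted({c for c, _ in pos | neg}))
            )
        if not self.sequence_ids:
            object.__setattr__(
                self, "sequence_ids", tuple(sorted({s for _, s in pos | neg}))
            )
        cset, sset = set(self.compound_ids), set(self.sequence_ids)
        for c, s in pos | neg:
            if c not in cset:
                raise FormatError(f"unregistered compound id {c!r}")
            if s not in sset:
                raise FormatError(f"unregistered sequence id {s!r}")

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    def restrict(self, pairs) -> "InteractionTable":
        """A new table holding only the given positive pairs."""
        pairs = frozenset(pairs)
        if not pairs <= self.positives:
            raise ValueError("restrict() called with pairs outside the table")
        return InteractionTable(pairs, frozenset(),
                                self.compound_ids, self.sequence_ids)


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of one compound; each bond stored once, undirected."""

    node_features: np.ndarray  # (n_nodes, NODE_FEATURE_DIM)
    edge_list: np.ndarray      # (n_edges, 2) int
    edge_features: np.ndarray  # (n_edges, EDGE_FEATURE_DIM)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_list.shape[0]


@dataclass(frozen=True)
class EncodedSequence:
    """Integer-tokenized protein sequence of fixed length."""

    tokens: np.ndarray  # (L_max,) int
    original_length: int


@dataclass(frozen=True)
class ReactionRecord:
    """One biochemical reaction b = {R, E, P} with its class labels."""

    reaction_id: str
    reactant_ids: tuple[str, ...]
    product_ids: tuple[str, ...]
    enzyme_ids: tuple[str, ...]
    rclass_id: str = ""
    ec_number: str = ""

    def __post_init__(self):
        for name in ("reactant_ids", "product_ids", "enzyme_ids"):
            if not getattr(self, name):
                raise FormatError(f"reaction {self.reaction_id!r}: empty {name}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_interactions(
    path,
    compound_column: str = "compound_id",
    sequence_column: str = "sequence_id",
    label_column: str | None = None,
) -> InteractionTable:
    """Read a TSV interaction table.

    Rows without a label column (or with label 1) are positives; label 0
    rows are labelled negatives. Duplicate rows are collapsed (count
    logged); a pair carrying both labels raises :class:`PairConflictError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (compound_column, sequence_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if label_column is None and "label" in df.columns:
        label_column = "label"
    if label_column is not None and label_column not in df.columns:
        raise FormatError(f"{path}: missing column {label_column!r}")

    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    comp_order: dict[str, None] = {}
    seq_order: dict[str, None] = {}
    n_dup = 0
    for row in df.itertuples(index=False):
        c = getattr(row, compound_column)
        s = getattr(row, sequence_column)
        pair = (str(c), str(s))
        label = 1
        if label_column is not None:
            label = int(getattr(row, label_column))
        target = positives if label == 1 else negatives
        other = negatives if label == 1 else positives
        if pair in other:
            raise PairConflictError(f"pair {pair} appears with both labels")
        if pair in target:
            n_dup += 1
        target.add(pair)
        comp_order.setdefault(pair[0])
        seq_order.setdefault(pair[1])
    if n_dup:
        logger.info("read_interactions(%s): collapsed %d duplicate rows", path, n_dup)
    return InteractionTable(
        frozenset(positives), frozenset(negatives),
        tuple(comp_order), tuple(seq_order),
    )


def write_interactions(table: InteractionTable, path) -> None:
    rows = [(c, s, 1) for c, s in sorted(table.positives)]
    rows += [(c, s, 0) for c, s in sorted(table.negatives)]
    df = pd.DataFrame(rows, columns=["compound_id", "sequence_id", "label"])
    if not table.negatives:
        df = df[["compound_id", "sequence_id"]]
    df.to_csv(path, sep="\t", index=False)


def read_compounds(path) -> dict[str, str]:
    """TSV of compound_id, smiles -> ordered dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("compound_id", "smiles"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["compound_id"], df["smiles"]))


def write_compounds(compounds: dict[str, str], path) -> None:
    pd.DataFrame(compounds.items(), columns=["compound_id", "smiles"]).to_csv(
        path, sep="\t", index=False
    )


def read_sequences(path) -> dict[str, str]:
    """FASTA -> {sequence_id: amino-acid string}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_sequences(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def read_reactions(path) -> list[ReactionRecord]:
    """TSV with columns reaction_id, reactants, products, enzymes, rclass, ec."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["reaction_id", "reactants", "products", "enzymes"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        def split(raw, _row=row):
            return tuple(x for x in str(raw).split(MULTI_VALUE_DELIMITER) if x)

        rec = ReactionRecord(
            reaction_id=str(row.reaction_id),
            reactant_ids=split(row.reactants),
            product_ids=split(row.products),
            enzyme_ids=split(row.enzymes),
            rclass_id=str(getattr(row, "rclass", "") or ""),
            ec_number=str(getattr(row, "ec", "") or ""),
        )
        records.append(rec)
    return records


def write_reactions(records: list[ReactionRecord], path) -> None:
    rows = [
        (
            r.reaction_id,
            MULTI_VALUE_DELIMITER.join(r.reactant_ids),
            MULTI_VALUE_DELIMITER.join(r.product_ids),
            MULTI_VALUE_DELIMITER.join(r.enzyme_ids),
            r.rclass_id,
            r.ec_number,
        )
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["reaction_id", "reactants", "products", "enzymes", "rclass", "ec"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _atom_features(atom: Chem.Atom) -> list[float]:
    onehot = [0.0] * (len(ATOM_VOCAB) + 1)
    sym = atom.GetSymbol()
    onehot[ATOM_VOCAB.index(sym) if sym in ATOM_VOCAB else len(ATOM_VOCAB)] = 1.0
    return onehot + [
        atom.GetMass() / 100.0,
        float(atom.GetTotalValence()),
        float(atom.IsInRing()),
        float(atom.GetFormalCharge()),
        float(atom.GetNumRadicalElectrons()),
        float(int(atom.GetChiralTag())),
        float(atom.GetDegree()),
        float(atom.GetTotalNumHs()),
        float(atom.GetIsAromatic()),
    ]


def _bond_features(bond: Chem.Bond) -> list[float]:
    btype = [float(bond.GetBondType() == t) for t in BOND_TYPES]
    stereo = [0.0] * N_STEREO
    stereo[min(int(bond.GetStereo()), N_STEREO - 1)] = 1.0
    return btype + [float(bond.IsInRing()), float(bond.GetIsConjugated())] + stereo


def featurize_compound(smiles: str) -> MolecularGraph:
    """SMILES -> heavy-atom :class:`MolecularGraph` (hydrogens implicit)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SMILESParseError(smiles)
    nodes = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    nodes = nodes.reshape(mol.GetNumAtoms(), NODE_FEATURE_DIM)
    edges = []
    efeat = []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        efeat.append(_bond_features(bond))
    edge_list = np.array(edges, dtype=np.int64).reshape(len(edges), 2)
    edge_features = np.array(efeat, dtype=np.float64).reshape(len(edges), EDGE_FEATURE_DIM)
    return MolecularGraph(nodes, edge_list, edge_features)


def encode_sequence(aa_string: str, L_max: int = 1000) -> EncodedSequence:
    """Tokenize an amino-acid string to a fixed length.

    Shorter sequences are right-padded with the 0 token; longer ones are
    truncated to the first ``L_max`` residues. Any residue outside the 20
    standard letters maps to the single unknown token.
    """
    if not aa_string:
        raise ValueError("empty amino-acid string")
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    tokens = np.zeros(L_max, dtype=np.int64)
    for i, aa in enumerate(aa_string[:L_max]):
        tokens[i] = _AA_INDEX.get(aa.upper(), UNKNOWN_TOKEN)
    return EncodedSequence(tokens, original_length=len(aa_string))
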