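"""View encoders: graph-convolutional compound encoder, 1D-CNN sequence
encoder, and their weight-tied (Siamese) pair variants.

Dimension convention. Within one contrastive phase every view must embed
into the same dimension. A pair view concatenates two weight-tied arm
outputs of dimension d', so the lone-object encoder of the opposite view
outputs 2 d' directly. The default d' is 32, giving 64-dimensional view
embeddings; the sizes below favour CPU-scale training and are configurable.

The GCN aggregates node features through symmetric-normalized adjacency
convolutions (A_hat = D^-1/2 (A + I) D^-1/2), pools nodes symmetrically
(mean by default, so embeddings are invariant to atom reindexing), and
finishes with two fully connected layers. The CNN embeds residue tokens,
applies same-padded convolution blocks, global-max-pools over positions
and projects with one fully connected layer. By default convolutions run
over the padded tensor; with ``mask_padding`` the padding positions are
excluded from the max pool, making the embedding independent of anything
beyond the sequence's original length.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .data import ALPHABET_SIZE, NODE_FEATURE_DIM, EncodedSequence, MolecularGraph
from .nn import MLP, Conv1d, Dense, Embedding, Module, Tensor, concatenate


@dataclass(frozen=True)
class EncoderConfig:
    embed_dim: int = 32          # d': single-arm embedding size; views are 2*d'
    gcn_layers: int = 3
    gcn_hidden: int = 64
    cnn_channels: tuple[int, ...] = (16, 32)
    cnn_kernel_sizes: tuple[int, ...] = (7, 7)
    residue_embed_dim: int = 16
    pooling: str = "mean"
    mask_padding: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be positive")
        if len(self.cnn_channels) != len(self.cnn_kernel_sizes):
            raise ValueError("cnn_channels and cnn_kernel_sizes must align")
        if self.pooling not in ("mean", "sum", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


# ---------------------------------------------------------------------------
# graph batching
# ---------------------------------------------------------------------------

def batch_graphs(graphs: list[MolecularGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad graphs to a common node count.

    Returns (X, A_hat, mask): node features (B, n, F), symmetric-normalized
    adjacency with self-loops (B, n, n) and a node mask (B, n, 1).
    """
    if not graphs:
        raise ValueError("empty graph batch")
    n_max = max(g.n_nodes for g in graphs)
    B = len(graphs)
    X = np.zeros((B, n_max, NODE_FEATURE_DIM))
    A = np.zeros((B, n_max, n_max))
    mask = np.zeros((B, n_max, 1))
    for b, g in enumerate(graphs):
        n = g.n_nodes
        if n == 0:
            raise ValueError("empty molecular graph")
        X[b, :n] = g.node_features
        adj = np.eye(n)
        for i, j in g.edge_list:
            adj[i, j] = 1.0
            adj[j, i] = 1.0
        dinv = 1.0 / np.sqrt(adj.sum(axis=1))
        A[b, :n, :n] = adj * dinv[:, None] * dinv[None, :]
        mask[b, :n] = 1.0
    return X, A, mask


class GCNEncoder(Module):
    """Graph-convolution stack + symmetric pooling + two FC layers."""

    def __init__(self, out_dim: int, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        dims = [NODE_FEATURE_DIM] + [config.gcn_hidden] * config.gcn_layers
        for i in range(config.gcn_layers):
            setattr(self, f"conv{i}", Dense(dims[i], dims[i + 1], rng))
        self.fc1 = Dense(config.gcn_hidden, config.gcn_hidden, rng)
        self.fc2 = Dense(config.gcn_hidden, out_dim, rng)
        self.out_dim = out_dim

    def forward_batch(self, X: np.ndarray, A: np.ndarray, mask: np.ndarray) -> Tensor:
        H = Tensor(X)
        A_t = Tensor(A)
        mask_t = Tensor(mask)
        for i in range(self.config.gcn_layers):
            H = (A_t @ getattr(self, f"conv{i}")(H)).relu() * mask_t
        if self.config.pooling == "mean":
            pooled = H.sum(axis=1) / Tensor(mask.sum(axis=1))
        elif self.config.pooling == "sum":
            pooled = H.sum(axis=1)
        else:  # max over real nodes; padding rows are zero after masking
            pooled = (H + Tensor((mask - 1.0) * 1e9)).max(axis=1)
        return self.fc2(self.fc1(pooled).relu())

    def encode(self, graphs: list[MolecularGraph]) -> Tensor:
        return self.forward_batch(*batch_graphs(graphs))

    def encode_one(self, graph: MolecularGraph) -> np.ndarray:
        return self.encode([graph]).data[0]


class CNNEncoder(Module):
    """Residue embedding + same-padded conv blocks + global max pool + FC."""

    def __init__(self, out_dim: int, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.embedding = Embedding(ALPHABET_SIZE + 1, config.residue_embed_dim, rng)
        dims = [config.residue_embed_dim] + list(config.cnn_channels)
        for i, k in enumerate(config.cnn_kernel_sizes):
            setattr(self, f"conv{i}", Conv1d(dims[i], dims[i + 1], k, rng))
        self.fc = Dense(dims[-1], out_dim, rng)
        self.out_dim = out_dim

    def forward_tokens(self, tokens: np.ndarray) -> Tensor:
        H = self.embedding(tokens)  # (B, L, E)
        for i in range(len(self.config.cnn_kernel_sizes)):
            H = getattr(self, f"conv{i}")(H).relu()
        if self.config.mask_padding:
            pad = (tokens == 0).astype(float)[:, :, None]
            H = H + Tensor(pad * -1e9)
        return self.fc(H.max(axis=1))

    def encode(self, sequences: list[EncodedSequence]) -> Tensor:
        tokens = np.stack([s.tokens for s in sequences])
        return self.forward_tokens(tokens)

    def encode_one(self, seq: EncodedSequence) -> np.ndarray:
        return self.encode([seq]).data[0]


# ---------------------------------------------------------------------------
# functional surface used by the training pipeline and tests
# ---------------------------------------------------------------------------

def encode_compound(graph: MolecularGraph, encoder: GCNEncoder) -> np.ndarray:
    """Embed one compound graph; output length is the encoder's out_dim."""
    if graph.n_nodes == 0:
        raise ValueError("empty molecular graph")
    return encoder.encode_one(graph)


def encode_sequence_cnn(seq: EncodedSequence, encoder: CNNEncoder) -> np.ndarray:
    """Embed one tokenized sequence."""
    return encoder.encode_one(seq)


def encode_sequence_pair(
    seq_i: EncodedSequence, seq_j: EncodedSequence, encoder: CNNEncoder
) -> np.ndarray:
    """Siamese pair embedding: shared-weight arms, concatenated (dim 2*d')."""
    z = encoder.encode([seq_i, seq_j]).data
    return np.concatenate([z[0], z[1]])


def encode_compound_pair(
    graph_i: MolecularGraph, graph_j: MolecularGraph, encoder: GCNEncoder
) -> np.ndarray:
    """Siamese pair embedding over the GCN arm."""
    z = encoder.encode([graph_i, graph_j]).data
    return np.concatenate([z[0], z[1]])


def encode_pairs_t(encoder, left: list, right: list) -> Tensor:
    """Differentiable batched Siamese pair embedding (k, 2*d')."""
    zl = encoder.encode(left)
    zr = encoder.encode(right)
    return concatenate([zl, zr], axis=1)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path, modules: dict[str, Module], config: EncoderConfig,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint: versioned config JSON + all weights."""
    arrays = {}
    for mname, mod in modules.items():
        for pname, arr in mod.state_dict().items():
            arrays[f"{mname}/{pname}"] = arr
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(config),
        "modules": list(modules),
        "extra": extra or {},
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, dict[str, np.ndarray]], EncoderConfig, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        states: dict[str, dict[str, np.ndarray]] = {m: {} for m in meta["modules"]}
        for key in npz.files:
            if key == "__meta__":
                continue
            mname, pname = key.split("/", 1)
            states[mname][pname] = npz[key]
    cfg_raw = meta["config"]
    for f in ("cnn_channels", "cnn_kernel_sizes"):
        cfg_raw[f] = tuple(cfg_raw[f])
    return states, EncoderConfig(**cfg_raw), meta["extra"]
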