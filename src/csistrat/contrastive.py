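"""Temperature-scaled contrastive objective over congruent view batches.

The discriminator scores a pair of view embeddings with the exponential of
their cosine similarity divided by a temperature tau. The directed batch
loss is an InfoNCE-style softmax cross-entropy: for each anchor n in a
batch of k aligned embedding pairs, the congruent partner (row n of the
other view) competes against the other k - 1 in-batch embeddings, which
are non-congruent because each batch row comes from a distinct key:

    L(V1 -> V2) = (1/k) sum_n -log[ h(z1_n, z2_n) / sum_m h(z1_n, z2_m) ]

The total two-view loss is the sum of the two directions; with three or
more views the loss is summed over all unordered view pairs, each pair
weighted equally.

Functions here accept plain numpy arrays and return floats; Tensor-valued
variants (suffix ``_t``) run on the autograd engine and are what training
differentiates. Log-sum-exp is computed with max-subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .nn import Tensor

NORM_EPS = 1e-12


@dataclass(frozen=True)
class ContrastiveConfig:
    temperature: float = 0.07
    batch_size: int = 8

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def discriminator(z1: np.ndarray, z2: np.ndarray, tau: float = 0.07) -> float:
    """exp(cos(z1, z2) / tau); symmetric and scale-invariant in its vectors."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape or z1.ndim != 1:
        raise ValueError("discriminator expects two equal-length vectors")
    n1, n2 = np.linalg.norm(z1), np.linalg.norm(z2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero vector passed to discriminator")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(z1 @ z2 / (n1 * n2) / tau))


def _check_batches(Z1: np.ndarray, Z2: np.ndarray) -> None:
    if Z1.ndim != 2 or Z2.ndim != 2:
        raise ValueError("embedding batches must be 2D (k x m)")
    if Z1.shape != Z2.shape:
        raise ValueError(f"batch shapes differ: {Z1.shape} vs {Z2.shape}")
    if np.any(np.linalg.norm(Z1, axis=1) == 0) or np.any(np.linalg.norm(Z2, axis=1) == 0):
        raise ValueError("zero embedding row in batch")


def _normalize_rows_t(Z: Tensor) -> Tensor:
    sq = (Z * Z).sum(axis=1, keepdims=True)
    return Z / (sq + NORM_EPS).sqrt()


def _logits_t(Z1: Tensor, Z2: Tensor, tau: float) -> Tensor:
    return (_normalize_rows_t(Z1) @ _normalize_rows_t(Z2).T) * (1.0 / tau)


def contrastive_loss_directed_t(Z1: Tensor, Z2: Tensor, tau: float) -> Tensor:
    """Directed loss with V1 as anchor, differentiable."""
    S = _logits_t(Z1, Z2, tau)
    smax = Tensor(S.data.max(axis=1, keepdims=True))  # constant shift
    lse = ((S - smax).exp().sum(axis=1)).log() + smax.reshape(-1)
    return (lse - S.diagonal()).mean()


def total_loss_t(Z1: Tensor, Z2: Tensor, tau: float) -> Tensor:
    return contrastive_loss_directed_t(Z1, Z2, tau) + contrastive_loss_directed_t(Z2, Z1, tau)


def multiview_loss_t(batches: list[Tensor], tau: float) -> Tensor:
    if len(batches) < 2:
        raise ValueError("multiview loss needs at least two views")
    total = None
    for Za, Zb in combinations(batches, 2):
        term = total_loss_t(Za, Zb, tau)
        total = term if total is None else total + term
    return total


def contrastive_loss_directed(Z1, Z2, tau: float = 0.07) -> float:
    """Directed in-batch loss, V1 anchoring, over aligned k x m batches."""
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    _check_batches(Z1, Z2)
    if tau <= 0:
        raise ValueError("temperature must be positive")
    return float(contrastive_loss_directed_t(Tensor(Z1), Tensor(Z2), tau).data)


def total_loss(Z1, Z2, tau: float = 0.07) -> float:
    """Symmetric two-view loss: both anchoring directions summed."""
    return contrastive_loss_directed(Z1, Z2, tau) + contrastive_loss_directed(Z2, Z1, tau)


def multiview_loss(batches, tau: float = 0.07) -> float:
    """Pairwise total loss summed over all unordered view pairs."""
    if len(batches) < 2:
        raise ValueError("multiview loss needs at least two views")
    return float(sum(total_loss(Za, Zb, tau) for Za, Zb in combinations(batches, 2)))


def per_anchor_diagnostics(Z1, Z2, tau: float = 0.07) -> list[dict]:
    """Training-log diagnostics per anchor: rank of the congruent partner
    among the k candidates (1 = best) and the mean non-congruent cosine."""
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    _check_batches(Z1, Z2)
    N1 = Z1 / np.linalg.norm(Z1, axis=1, keepdims=True)
    N2 = Z2 / np.linalg.norm(Z2, axis=1, keepdims=True)
    cos = N1 @ N2.T
    k = cos.shape[0]
    out = []
    for n in range(k):
        row = cos[n]
        rank = int(1 + np.sum(row > row[n]))
        neg_mean = float((row.sum() - row[n]) / (k - 1)) if k > 1 else float("nan")
        out.append({"anchor": n, "congruent_rank": rank, "mean_noncongruent_cosine": neg_mean})
    return out
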