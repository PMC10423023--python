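"""Contrastive discriminator and batch losses vs explicit oracles."""

import numpy as np
import pytest

import csistrat as cs
from csistrat.contrastive import contrastive_loss_directed_t, per_anchor_diagnostics
from csistrat.nn import Tensor


def oracle_directed(Z1, Z2, tau):
    """Explicit double-loop InfoNCE."""
    k = Z1.shape[0]
    total = 0.0
    for n in range(k):
        num = cs.discriminator(Z1[n], Z2[n], tau)
        den = sum(cs.discriminator(Z1[n], Z2[m], tau) for m in range(k))
        total += -np.log(num / den)
    return total / k


class TestDiscriminator:
    def test_identical_vectors_at_paper_temperature(self):
        z = np.array([1.0, 0.0])
        assert cs.discriminator(z, z, 0.07) == pytest.approx(np.exp(1 / 0.07))

    def test_orthogonal_gives_one(self):
        assert cs.discriminator(np.array([1.0, 0]), np.array([0, 1.0]), 0.3) == pytest.approx(1.0)

    def test_scale_invariance_and_symmetry(self):
        z1, z2 = np.array([3.0, 0]), np.array([1.0, 0])
        assert cs.discriminator(z1, z2, 0.07) == pytest.approx(np.exp(1 / 0.07))
        a, b = np.random.default_rng(0).normal(size=(2, 6))
        assert cs.discriminator(a, b, 0.1) == pytest.approx(cs.discriminator(b, a, 0.1))

    def test_errors(self):
        with pytest.raises(ValueError):
            cs.discriminator(np.zeros(3), np.ones(3), 0.07)
        with pytest.raises(ValueError):
            cs.discriminator(np.ones(3), np.ones(4), 0.07)
        with pytest.raises(ValueError):
            cs.discriminator(np.ones(3), np.ones(3), 0.0)


class TestDirectedLoss:
    def test_k1_exactly_zero(self):
        rng = np.random.default_rng(1)
        Z1, Z2 = rng.normal(size=(2, 1, 8))
        assert cs.contrastive_loss_directed(Z1, Z2, 0.07) == 0.0

    @pytest.mark.parametrize("k", [2, 4, 8, 64])
    def test_identical_embeddings_give_log_k(self, k):
        Z = np.tile(np.array([1.0, 2.0, -1.0]), (k, 1))
        assert cs.contrastive_loss_directed(Z, Z, 0.07) == pytest.approx(np.log(k), abs=1e-9)

    def test_matches_double_loop_oracle_on_random_batches(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            k = int(rng.integers(2, 17))
            m = int(rng.integers(2, 33))
            tau = float(rng.uniform(0.05, 1.0))
            Z1, Z2 = rng.normal(size=(2, k, m))
            got = cs.contrastive_loss_directed(Z1, Z2, tau)
            assert got == pytest.approx(oracle_directed(Z1, Z2, tau), abs=1e-6)
            assert got >= 0.0

    def test_batch_size_mismatch(self):
        with pytest.raises(ValueError):
            cs.contrastive_loss_directed(np.ones((3, 4)), np.ones((2, 4)), 0.07)

    def test_bounded_logits_upper_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(2, 10))
            Z1, Z2 = rng.normal(size=(2, k, 6))
            tau = float(rng.uniform(0.05, 0.5))
            assert cs.contrastive_loss_directed(Z1, Z2, tau) <= 2 / tau + np.log(k) + 1e-9


class TestTotalAndMultiview:
    def test_identical_batches_2logk(self):
        Z = np.tile(np.arange(1.0, 5.0), (4, 1))
        assert cs.total_loss(Z, Z, 0.07) == pytest.approx(2 * np.log(4), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        Z1, Z2 = rng.normal(size=(2, 6, 12))
        assert abs(cs.total_loss(Z1, Z2, 0.07) - cs.total_loss(Z2, Z1, 0.07)) < 1e-9

    def test_total_equals_sum_of_directions(self):
        rng = np.random.default_rng(8)
        Z1, Z2 = rng.normal(size=(2, 5, 9))
        assert cs.total_loss(Z1, Z2, 0.2) == pytest.approx(
            oracle_directed(Z1, Z2, 0.2) + oracle_directed(Z2, Z1, 0.2), abs=1e-6
        )

    def test_three_identical_views(self):
        Z = np.tile(np.arange(1.0, 4.0), (4, 1))
        assert cs.multiview_loss([Z, Z, Z], 0.07) == pytest.approx(6 * np.log(4), abs=1e-9)

    def test_two_views_degenerate_to_total(self):
        rng = np.random.default_rng(9)
        Z1, Z2 = rng.normal(size=(2, 4, 8))
        assert cs.multiview_loss([Z1, Z2], 0.1) == pytest.approx(cs.total_loss(Z1, Z2, 0.1))

    def test_three_views_equal_oracle_sum(self):
        rng = np.random.default_rng(10)
        Zs = list(rng.normal(size=(3, 6, 8)))
        expected = sum(
            oracle_directed(a, b, 0.07) + oracle_directed(b, a, 0.07)
            for i, a in enumerate(Zs) for b in Zs[i + 1:]
        )
        assert cs.multiview_loss(Zs, 0.07) == pytest.approx(expected, abs=1e-6)

    def test_fewer_than_two_views_error(self):
        with pytest.raises(ValueError):
            cs.multiview_loss([np.ones((2, 3))], 0.07)


def test_monotone_increasing_in_tau_at_ideal_geometry():
    """Congruent cosine 1, non-congruent 0: loss grows with temperature."""
    k = 4
    Z1 = np.eye(k)
    Z2 = np.eye(k)
    taus = [0.05, 0.06, 0.07, 0.08, 0.2, 0.5, 1.0]
    losses = [cs.contrastive_loss_directed(Z1, Z2, t) for t in taus]
    assert all(a < b for a, b in zip(losses, losses[1:]))


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(42)
    Z1d = rng.normal(size=(4, 8))
    Z2d = rng.normal(size=(4, 8))
    tau = 0.07
    Z1 = Tensor(Z1d.copy(), requires_grad=True)
    Z2 = Tensor(Z2d.copy(), requires_grad=True)
    contrastive_loss_directed_t(Z1, Z2, tau).backward()
    eps = 1e-6
    for T, arr in ((Z1, Z1d), (Z2, Z2d)):
        num = np.zeros_like(arr)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                orig = arr[i, j]
                arr[i, j] = orig + eps
                fp = cs.contrastive_loss_directed(Z1d, Z2d, tau)
                arr[i, j] = orig - eps
                fm = cs.contrastive_loss_directed(Z1d, Z2d, tau)
                arr[i, j] = orig
                num[i, j] = (fp - fm) / (2 * eps)
        scale = np.maximum(np.abs(num), 1e-8)
        assert np.max(np.abs(T.grad - num) / scale) < 1e-4


def test_per_anchor_diagnostics_rank():
    Z1 = np.eye(3)
    Z2 = np.eye(3)
    diags = per_anchor_diagnostics(Z1, Z2, 0.07)
    assert all(d["congruent_rank"] == 1 for d in diags)
    assert all(d["mean_noncongruent_cosine"] == pytest.approx(0.0) for d in diags)
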