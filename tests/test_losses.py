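"""Contrastive loss system: oracles, worked values, and mechanism invariants."""

import numpy as np
import pytest

from reefclr.autodiff import Tensor
from reefclr.losses import (
    FeatureBank,
    composite_loss,
    compute_weights,
    cosine_matrix,
    ema_update,
    l2_normalize,
    multi_positive_nt_xent,
    one_hot_weights,
    simsiam_loss,
    standard_pairing,
    supcon_weights,
    vanilla_mode,
    vicreg_loss,
)

from conftest import random_unit_vectors


def brute_force_nt_xent(z, pair_of, tau, bank=None):
    """Independent textbook NT-Xent: explicit loops, no shared code path."""
    z = np.asarray(z, dtype=float)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    neg = list(z) + (list(bank) if bank is not None else [])
    total = 0.0
    for i in range(len(z)):
        j = pair_of[i]
        num = np.exp(np.dot(z[i], z[j]) / tau)
        den = sum(
            np.exp(np.dot(z[i], v) / tau)
            for l, v in enumerate(neg) if l != i
        )
        total += -np.log(num / den)
    return total / len(z)


class TestCosineMatrix:
    def test_identity_and_antipode(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        s = cosine_matrix(x, x)
        assert np.allclose(np.diag(s), 1.0)
        assert np.allclose(s[0, 1], 0.0)
        assert np.isclose(cosine_matrix(x[:1], -x[:1])[0, 0], -1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            cosine_matrix(np.zeros((1, 3)), np.ones((1, 3)))


class TestWeightMatrix:
    def test_no_soft_positives_gives_one_hot(self, rng):
        t = random_unit_vectors(rng, 8, 16)  # random dirs: sims ~0 < theta
        pair = standard_pairing(8)
        w = compute_weights(t, pair, theta=0.99, k=5)
        expected = np.zeros((8, 8))
        expected[np.arange(8), pair] = 1.0
        assert np.allclose(w.W, expected)

    def test_worked_soft_neighbor_row(self):
        # anchor 0: paired view 1, plus neighbor 2 at teacher similarity 0.9
        c, s = 0.9, np.sqrt(1 - 0.9**2)
        t = np.array([[1.0, 0.0], [0.0, 1.0], [c, s], [-1.0, 0.0]])
        w = compute_weights(t, standard_pairing(4), theta=0.7, k=5)
        assert w.W[0, 1] == pytest.approx(1 / 1.95, abs=1e-4)
        assert w.W[0, 2] == pytest.approx(0.95 / 1.95, abs=1e-4)

    def test_rows_sum_to_one_diagonal_zero(self, rng):
        for trial in range(20):
            t = random_unit_vectors(rng, 12, 4)  # low dim: soft positives occur
            w = compute_weights(t, standard_pairing(12), theta=0.5, k=3)
            assert np.allclose(w.W.sum(axis=1), 1.0)
            assert np.allclose(np.diag(w.W), 0.0)

    def test_top_k_limit(self, rng):
        t = np.tile(np.array([[1.0, 0.0]]), (10, 1))  # all identical: sims = 1
        w = compute_weights(t, standard_pairing(10), theta=0.7, k=3)
        # paired + exactly k soft positives
        assert np.count_nonzero(w.W[0]) == 4

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.zeros((0, 4)), np.array([], dtype=int))


class TestSupConWeights:
    def test_all_distinct_reduces_to_pairing(self):
        pair = standard_pairing(6)
        labels = ["a", "a", "b", "b", "c", "c"]
        w = supcon_weights(labels, pair)
        expected = np.zeros((6, 6))
        expected[np.arange(6), pair] = 1.0
        assert np.allclose(w.W, expected)

    def test_all_same_label_uniform(self):
        w = supcon_weights(["x"] * 4, standard_pairing(4))
        assert np.allclose(w.W.sum(axis=1), 1.0)
        assert np.allclose(w.W[0, 1:], 1.0 / 3.0)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            supcon_weights(["a", None, "a", "a"], standard_pairing(4))


class TestNTXent:
    def test_worked_value(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        loss = vanilla_mode(z, tau=1.0)
        assert float(loss.data) == pytest.approx(np.log(1 + 2 / np.e), abs=1e-9)

    def test_single_identical_pair_zero(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert float(vanilla_mode(z, tau=0.5).data) == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence_100_batches(self, rng):
        """Full engine with theta>1, M=0 equals brute-force NT-Xent to 1e-6."""
        for trial in range(100):
            b = int(rng.integers(2, 9))
            d = int(rng.integers(2, 17))
            z = random_unit_vectors(rng, 2 * b, d)
            tau = float(rng.uniform(0.1, 1.0))
            pair = standard_pairing(2 * b)
            w = compute_weights(z, pair, theta=1.1, k=5)  # theta>1: no soft pos
            ours = float(multi_positive_nt_xent(z, None, w, tau).data)
            oracle = brute_force_nt_xent(z, pair, tau)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_bank_negatives_in_oracle(self, rng):
        b, d = 4, 8
        z = random_unit_vectors(rng, 2 * b, d)
        bank = random_unit_vectors(rng, 10, d)
        pair = standard_pairing(2 * b)
        w = one_hot_weights(pair, bank_size=10)
        ours = float(multi_positive_nt_xent(z, bank, w, 0.3).data)
        assert ours == pytest.approx(brute_force_nt_xent(z, pair, 0.3, bank), abs=1e-6)

    def test_bank_monotonicity(self, rng):
        """Adding a negative near an anchor strictly increases the loss."""
        z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        pair = standard_pairing(4)
        base = float(multi_positive_nt_xent(z, None, one_hot_weights(pair), 1.0).data)
        bank = np.array([[0.0, 1.0]])  # identical to anchor 0's negatives
        more = float(
            multi_positive_nt_xent(z, bank, one_hot_weights(pair, bank_size=1), 1.0).data
        )
        assert more > base

    def test_bad_temperature_rejected(self):
        z = np.eye(2)
        with pytest.raises(ValueError):
            multi_positive_nt_xent(z, None, one_hot_weights(standard_pairing(2)), 0.0)

    def test_gradient_matches_finite_difference(self, rng):
        raw = rng.normal(size=(8, 6))
        pair = standard_pairing(8)
        w = compute_weights(raw / np.linalg.norm(raw, axis=1, keepdims=True), pair, 0.5, 2)

        def f(arr):
            zt = l2_normalize(Tensor(arr, requires_grad=True))
            return multi_positive_nt_xent(zt, None, w, 0.4)

        t = Tensor(raw, requires_grad=True)
        loss = multi_positive_nt_xent(l2_normalize(t), None, w, 0.4)
        loss.backward()
        eps = 1e-6
        for _ in range(5):
            i, j = rng.integers(0, 8), rng.integers(0, 6)
            pert = raw.copy()
            pert[i, j] += eps
            up = float(f(pert).data)
            pert[i, j] -= 2 * eps
            dn = float(f(pert).data)
            assert t.grad[i, j] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)


class TestFeatureBank:
    def test_fifo_eviction(self):
        bank = FeatureBank(3, 2)
        for i in range(4):
            bank.push(np.array([[float(i), 0.0]]))
        assert len(bank) == 3
        assert bank.data[:, 0].tolist() == [1.0, 2.0, 3.0]

    def test_full_replacement(self):
        bank = FeatureBank(4, 2)
        bank.push(np.ones((4, 2)))
        bank.push(np.zeros((4, 2)))
        assert np.allclose(bank.data, 0.0)

    def test_capacity_never_exceeded(self, rng):
        bank = FeatureBank(5, 3)
        for _ in range(20):
            bank.push(rng.normal(size=(int(rng.integers(1, 8)), 3)))
            assert len(bank) <= 5


class TestEMA:
    def test_endpoints_and_arithmetic(self):
        t, s = [np.zeros(3)], [np.ones(3)]
        assert np.allclose(ema_update(t, s, 1.0)[0], 0.0)
        assert np.allclose(ema_update(t, s, 0.0)[0], 1.0)
        assert np.allclose(ema_update(t, s, 0.99)[0], 0.01)

    def test_geometric_convergence_to_constant_student(self):
        teacher, student = [np.zeros(4)], [np.ones(4)]
        gaps = []
        for _ in range(10):
            teacher = ema_update(teacher, student, 0.9)
            gaps.append(np.abs(teacher[0] - student[0]).max())
        ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
        assert np.allclose(ratios, 0.9, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ema_update([np.zeros(2)], [np.zeros(3)], 0.5)


class TestSimSiam:
    def test_aligned_views_give_minus_one(self):
        z = Tensor(np.array([[0.6, 0.8], [1.0, 0.0]]))
        loss = simsiam_loss([z], [z], predictor=lambda x: x)
        assert float(loss.data) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_views_zero(self):
        g = Tensor(np.array([[1.0, 0.0]]))
        l = Tensor(np.array([[0.0, 1.0]]))
        assert float(simsiam_loss([g], [l], lambda x: x).data) == pytest.approx(0.0)

    def test_stop_gradient_target_branch(self):
        """Gradient reaches the predictor input, not the target."""
        g = Tensor(np.array([[1.0, 0.2]]), requires_grad=True)
        l = Tensor(np.array([[0.4, 1.0]]), requires_grad=True)
        w = Tensor(np.eye(2) * 0.5, requires_grad=True)
        loss = simsiam_loss([g], [l.detach()], predictor=lambda x: x @ w)
        loss.backward()
        assert l.grad is None  # detached target contributed nothing
        assert np.abs(g.grad).sum() > 0
        assert np.abs(w.grad).sum() > 0


class TestVICReg:
    def test_identical_branches_zero_invariance(self, rng):
        z = rng.normal(size=(10, 4))
        loss_same = float(vicreg_loss(z, z, lambda_v=0.0, lambda_c=0.0).data)
        assert loss_same == pytest.approx(0.0, abs=1e-12)

    def test_collapsed_embeddings_hinge_one(self):
        z = np.ones((8, 5))
        loss = float(vicreg_loss(z, z, lambda_v=1.0, lambda_i=0.0, lambda_c=0.0).data)
        assert loss == pytest.approx(1.0, abs=1e-2)  # sqrt(eps) slack

    def test_decorrelated_unit_variance_near_zero(self, rng):
        # orthogonalized Gaussian sample with exactly unit variance per dim
        n, d = 200, 6
        g = rng.normal(size=(n, d))
        q, _ = np.linalg.qr(g - g.mean(axis=0))
        z = q * np.sqrt(n)  # columns orthonormal -> decorrelated, variance ~1
        loss = float(vicreg_loss(z, z, lambda_i=0.0).data)
        assert loss == pytest.approx(0.0, abs=1e-2)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            vicreg_loss(np.ones((1, 3)), np.ones((1, 3)))


class TestCompositeLoss:
    def test_linearity_and_zero_weights(self, rng):
        parts = rng.normal(size=3)
        b = composite_loss(*parts, alpha=1.0, beta=0.0, gamma=0.0)
        assert b.total == pytest.approx(parts[0])
        b2 = composite_loss(*parts, alpha=0.0, beta=0.0, gamma=0.0)
        assert b2.total == pytest.approx(0.0)
        b3 = composite_loss(*parts, alpha=2.0, beta=3.0, gamma=4.0)
        assert b3.total == pytest.approx(2 * parts[0] + 3 * parts[1] + 4 * parts[2], abs=1e-6)

    def test_non_finite_part_named(self):
        with pytest.raises(ValueError, match="l_siam"):
            composite_loss(1.0, np.nan, 0.0)
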