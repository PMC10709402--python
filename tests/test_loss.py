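"""Loss algebra: negative cosine similarity, symmetry, stop-gradient."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fpsiam import nn
from fpsiam.loss import LossBreakdown, fpsiam_loss, neg_cosine, symmetric_loss
from fpsiam.nn import Tensor


def brute_force_neg_cosine(p: np.ndarray, z: np.ndarray) -> float:
    """Independent oracle: normalise, dot, average — plain numpy."""
    p, z = np.atleast_2d(p), np.atleast_2d(z)
    vals = []
    for pi, zi in zip(p, z):
        vals.append(-np.dot(pi / np.linalg.norm(pi), zi / np.linalg.norm(zi)))
    return float(np.mean(vals))


class TestNegCosine:
    def test_self_similarity_is_minus_one(self):
        v = np.array([[3.0, -1.0, 2.0]])
        assert np.isclose(float(neg_cosine(v, v).data), -1.0, atol=1e-6)

    def test_orthogonal_is_zero(self):
        assert np.isclose(float(neg_cosine([[1.0, 0.0]], [[0.0, 1.0]]).data),
                          0.0, atol=1e-7)

    def test_known_value(self):
        got = float(neg_cosine([[1.0, 1.0]], [[1.0, 0.0]]).data)
        assert np.isclose(got, -1 / np.sqrt(2), atol=1e-6)

    def test_matches_brute_force_on_random_batch(self):
        rng = np.random.default_rng(17)
        p = rng.normal(size=(32, 8))
        z = rng.normal(size=(32, 8))
        assert np.isclose(float(neg_cosine(p, z).data),
                          brute_force_neg_cosine(p, z), atol=1e-6)

    def test_zero_norm_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            neg_cosine([[0.0, 0.0]], [[1.0, 0.0]])

    def test_epsilon_clamps_instead(self):
        val = float(neg_cosine([[0.0, 0.0]], [[1.0, 0.0]], eps=1e-4).data)
        assert np.isfinite(val)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(arrays(np.float64, (4, 6), elements=st.floats(-10, 10)),
           arrays(np.float64, (4, 6), elements=st.floats(-10, 10)))
    def test_bounds_property(self, p, z):
        if np.any(np.linalg.norm(p, axis=1) < 1e-6) or \
                np.any(np.linalg.norm(z, axis=1) < 1e-6):
            return
        val = float(neg_cosine(p, z).data)
        assert -1.0 - 1e-5 <= val <= 1.0 + 1e-5

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_scale_invariance(self, alpha, beta):
        rng = np.random.default_rng(5)
        p = rng.normal(size=(8, 5))
        z = rng.normal(size=(8, 5))
        a = float(neg_cosine(p, z).data)
        b = float(neg_cosine(alpha * p, beta * z).data)
        assert np.isclose(a, b, atol=1e-4)


class TestSymmetricLoss:
    def test_perfect_agreement(self):
        u = np.array([[0.6, 0.8]])
        assert np.isclose(float(symmetric_loss(u, u, u, u).data), -1.0,
                          atol=1e-6)

    def test_orthogonal_views(self):
        e1, e2 = np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])
        # p1 orthogonal to z2 and p2 orthogonal to z1
        assert np.isclose(float(symmetric_loss(e1, e1, e2, e2).data), 0.0,
                          atol=1e-7)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        p1, z1, p2, z2 = (rng.normal(size=(16, 10)) for _ in range(4))
        expected = 0.5 * brute_force_neg_cosine(p1, z2) + \
            0.5 * brute_force_neg_cosine(p2, z1)
        assert np.isclose(float(symmetric_loss(p1, z1, p2, z2).data),
                          expected, atol=1e-6)

    def test_swap_symmetry_exact(self):
        rng = np.random.default_rng(29)
        p1, z1, p2, z2 = (rng.normal(size=(8, 6)) for _ in range(4))
        a = float(symmetric_loss(p1, z1, p2, z2).data)
        b = float(symmetric_loss(p2, z2, p1, z1).data)
        assert a == b

    def test_stop_gradient_blocks_z_branch(self):
        """The gradient of D(p, stopgrad(z)) w.r.t. z-producing parameters
        is identically zero.

        Stop-gradient declares z a constant in the loss term; the
        finite-difference oracle therefore perturbs the z-branch weights
        while holding the stopped values at their recorded constants — the
        loss must not move — whereas the p-branch gradient is clearly
        nonzero and matches its own finite difference.
        """
        rng = np.random.default_rng(31)
        wp = nn.Linear(4, 4, rng=rng)
        wz = nn.Linear(4, 4, rng=rng)
        x1 = Tensor(rng.normal(size=(6, 4)))
        x2 = Tensor(rng.normal(size=(6, 4)))

        def loss(frozen_z=None):
            p1, p2 = wp(x1), wp(x2)
            if frozen_z is None:
                z1, z2 = wz(x1), wz(x2)
            else:
                z1, z2 = frozen_z
            return symmetric_loss(p1, z1, p2, z2)

        out = loss()
        out.backward()
        # autodiff: no gradient reaches the z branch at all
        assert wz.weight.grad is None or np.all(wz.weight.grad == 0)
        assert np.abs(wp.weight.grad).max() > 1e-4

        # finite-difference oracle on the function training differentiates:
        # z held at its recorded constants while wz is perturbed -> fd == 0
        z_const = (Tensor(wz(x1).data.copy()), Tensor(wz(x2).data.copy()))
        eps = 1e-3
        orig = wz.weight.data[0, 0]
        wz.weight.data[0, 0] = orig + eps
        lp = float(loss(frozen_z=z_const).data)
        wz.weight.data[0, 0] = orig - eps
        lm = float(loss(frozen_z=z_const).data)
        wz.weight.data[0, 0] = orig
        assert abs((lp - lm) / (2 * eps)) < 1e-8

        # p-branch: autodiff matches finite differences and is nonzero
        orig = wp.weight.data[0, 0]
        wp.weight.data[0, 0] = orig + eps
        lp = float(loss().data)
        wp.weight.data[0, 0] = orig - eps
        lm = float(loss().data)
        wp.weight.data[0, 0] = orig
        fd = (lp - lm) / (2 * eps)
        assert np.isclose(fd, wp.weight.grad[0, 0], rtol=5e-2, atol=1e-4)


class TestFPSiamLoss:
    def test_breakdown_arithmetic(self):
        b = LossBreakdown(L_local=-0.8, L_global=-0.6, lambda_weight=0.5,
                          L_total=-0.7)
        assert b.L_total == pytest.approx(-0.7)

    def test_breakdown_rejects_inconsistent_total(self):
        with pytest.raises(ValueError):
            LossBreakdown(L_local=-0.8, L_global=-0.6, lambda_weight=0.5,
                          L_total=-0.5)

    @pytest.fixture
    def batches(self):
        rng = np.random.default_rng(41)
        local = tuple(rng.normal(size=(8, 5)) for _ in range(4))
        global_ = tuple(rng.normal(size=(8, 5)) for _ in range(4))
        return local, global_

    def test_lambda_endpoints(self, batches):
        local, global_ = batches
        _, b0 = fpsiam_loss(local, global_, lambda_weight=0.0)
        _, b1 = fpsiam_loss(local, global_, lambda_weight=1.0)
        assert b0.L_total == b0.L_global
        assert b1.L_total == b1.L_local

    def test_half_lambda_is_mean_of_endpoints(self, batches):
        local, global_ = batches
        _, b0 = fpsiam_loss(local, global_, lambda_weight=0.0)
        _, b1 = fpsiam_loss(local, global_, lambda_weight=1.0)
        _, bh = fpsiam_loss(local, global_, lambda_weight=0.5)
        assert np.isclose(bh.L_total, 0.5 * (b0.L_total + b1.L_total),
                          atol=1e-6)

    def test_lambda_out_of_range_rejected(self, batches):
        local, global_ = batches
        with pytest.raises(ValueError, match="lambda"):
            fpsiam_loss(local, global_, lambda_weight=1.5)

    def test_terms_within_bounds(self, batches):
        local, global_ = batches
        _, b = fpsiam_loss(local, global_, lambda_weight=0.5)
        assert -1 <= b.L_local <= 1 and -1 <= b.L_global <= 1
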