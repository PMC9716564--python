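"""Layer contracts checked against brute-force oracles and finite differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bias3d.autodiff as ad
from bias3d.autodiff import Tensor
from bias3d.nn_layers import (
    LRNParams,
    conv2d,
    conv_block,
    conv_jkff_step,
    fcej_forward,
    flipflop_update,
    jkff_gradcheck,
    jkff_step,
    lrn,
    lrn_relu_pool,
    maxpool,
    relu,
    xavier_init,
)


from tests_oracles import conv_reference as conv_oracle
from tests_oracles import lrn_reference as lrn_oracle


class TestConv2d:
    def test_identity_kernel(self, rng):
        x = rng.random((1, 6, 6, 2))
        w = np.zeros((3, 3, 2, 2))
        w[1, 1] = np.eye(2)  # centre-tap identity
        assert np.allclose(conv2d(x, w).data, x)

    def test_constant_bias_on_zero_input(self):
        x = np.zeros((1, 4, 4, 1))
        w = np.zeros((3, 3, 1, 3))
        b = np.full(3, 0.5)
        assert np.allclose(conv2d(x, w, b).data, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(1, 5, 5, 2))
        w = rng.normal(size=(3, 3, 2, 3))
        b = rng.normal(size=3)
        assert np.allclose(conv2d(x, w, b).data, conv_oracle(x, w, b), atol=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv2d(rng.random((1, 4, 4, 2)), rng.random((3, 3, 3, 1)))


class TestRelu:
    def test_values_and_idempotence(self, rng):
        x = rng.normal(size=(4, 4))
        y = relu(x).data
        assert np.all(y >= 0)
        assert np.allclose(relu(y).data, y)
        assert relu(np.array([-1.0])).data[0] == 0.0
        assert relu(np.array([2.0])).data[0] == 2.0


class TestLRN:
    def test_single_channel_arithmetic(self):
        # x=2, (k, a, b, c) = (1, 1, 1, 1): 2 / (1 + 4) = 0.4
        out = lrn(np.full((1, 1, 1, 1), 2.0), LRNParams(1.0, 1.0, 1.0, 1))
        assert out.data.flat[0] == pytest.approx(0.4)

    def test_zero_input_stays_zero(self):
        out = lrn(np.zeros((1, 2, 2, 3)), LRNParams(1.0, 1.0, 1.0, 3))
        assert np.all(out.data == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(1, 4, 4, 6))
        p = LRNParams(2.0, 1e-4, 0.75, 5)
        assert np.allclose(
            lrn(x, p).data, lrn_oracle(x, 2.0, 1e-4, 0.75, 5), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_standard_setting_matches_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        x = rng.normal(size=(2, 3, 3, 4))
        assert np.allclose(
            lrn(x, LRNParams()).data, lrn_oracle(x, 0.0, 1.0, 1.0, 4), atol=1e-10
        )


class TestMaxpool:
    def test_single_block(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        assert maxpool(x).data.flat[0] == 4.0

    def test_constant_map(self):
        x = np.full((1, 16, 16, 2), 0.3)
        y = maxpool(x).data
        assert y.shape == (1, 8, 8, 2)
        assert np.all(y == 0.3)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            maxpool(np.zeros((1, 5, 5, 1)))


class TestFCEJ:
    def test_zero_contexts_reduce_to_plain_fc(self, rng):
        x = rng.normal(size=(1, 4))
        w_in = rng.normal(size=(4, 3))
        w_e = rng.normal(size=(3, 3))
        w_j = rng.normal(size=(2, 3))
        b = rng.normal(size=3)
        out = fcej_forward(x, np.zeros((1, 3)), np.zeros((1, 2)), (w_in, w_e, w_j), b)
        assert np.allclose(out.data, np.maximum(x @ w_in + b, 0.0))

    def test_zero_weights_give_relu_bias(self):
        b = np.array([-1.0, 0.5, 2.0])
        out = fcej_forward(
            np.ones((1, 4)), np.ones((1, 3)), np.ones((1, 2)),
            (np.zeros((4, 3)), np.zeros((3, 3)), np.zeros((2, 3))), b,
        )
        assert np.allclose(out.data, [[0.0, 0.5, 2.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matmul_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, e, j = rng.normal(size=(1, 4)), rng.normal(size=(1, 3)), rng.normal(size=(1, 2))
        w_in, w_e, w_j = (
            rng.normal(size=(4, 3)), rng.normal(size=(3, 3)), rng.normal(size=(2, 3))
        )
        b = rng.normal(size=3)
        expected = np.maximum(x @ w_in + e @ w_e + j @ w_j + b, 0.0)
        out = fcej_forward(x, e, j, (w_in, w_e, w_j), b)
        assert np.allclose(out.data, expected, atol=1e-6)


class TestFlipFlop:
    def test_truth_table(self):
        h = np.array([0.3])
        # hold: J=K=0
        assert flipflop_update(np.zeros(1), np.zeros(1), h).data == pytest.approx(0.3)
        # set from empty: H_prev=0 -> H=J
        assert flipflop_update(np.array([0.8]), np.zeros(1), np.zeros(1)).data == (
            pytest.approx(0.8)
        )
        # reset: H_prev=1, K=1 -> 0 regardless of J
        assert flipflop_update(np.array([0.6]), np.ones(1), np.ones(1)).data == (
            pytest.approx(0.0)
        )
        # toggle: J=K=1 -> 1-H
        assert flipflop_update(np.ones(1), np.ones(1), h).data == pytest.approx(0.7)

    def test_state_partials(self):
        """dH/dJ = 1 - H_prev and dH/dK = -H_prev."""
        hp = Tensor(np.array([0.3]))
        J = Tensor(np.array([0.4]), requires_grad=True)
        K = Tensor(np.array([0.9]), requires_grad=True)
        flipflop_update(J, K, hp).sum().backward()
        assert J.grad[0] == pytest.approx(0.7)
        assert K.grad[0] == pytest.approx(-0.3)

    def test_dense_layer_finite_difference(self, rng):
        x = rng.normal(size=(1, 4))
        h = rng.random((1, 3))
        w_j, w_k = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        w_out = rng.normal(size=(3, 3))
        assert jkff_gradcheck(x, h, w_j, w_k, w_out) <= 1e-5

    def test_hidden_state_stays_in_unit_interval(self, rng):
        """Induction property over 100 random steps."""
        w_j, w_k = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        w_out = rng.normal(size=(3, 3))
        H = np.ones((1, 3))
        for _ in range(100):
            x = rng.normal(size=(1, 4)) * 3.0
            O, Ht = jkff_step(x, H, w_j, w_k, w_out)
            H = Ht.data
            assert np.all(H >= 0.0) and np.all(H <= 1.0)

    def test_complementary_gates_collapse_to_gate_value(self):
        """With K = 1 - J the update J(1-H) + J*H = J: the state becomes a
        pure function of the gate, a degenerate convex-combination memory."""
        for j, h in [(0.25, 0.6), (0.9, 0.1), (0.5, 0.5)]:
            J = np.array([j])
            out = flipflop_update(J, 1.0 - J, np.array([h]))
            assert out.data[0] == pytest.approx(j)

    def test_first_step_from_ones_is_one_minus_K(self, rng):
        x = rng.normal(size=(1, 2))
        w_j, w_k = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        w_out = np.eye(2)
        _, H1 = jkff_step(x, np.ones((1, 2)), w_j, w_k, w_out)
        from scipy.special import expit

        inp = np.concatenate([x, np.ones((1, 2))], axis=1)
        K = expit(inp @ w_k)
        assert np.allclose(H1.data, 1.0 - K, atol=1e-7)


class TestConvFlipFlop:
    def test_agrees_with_dense_at_1x1(self, rng):
        """With 1x1 kernels and 1x1 spatial maps, conv and dense flip-flop
        layers are the same function."""
        x = rng.normal(size=(1, 1, 1, 4))
        h = rng.random((1, 1, 1, 3))
        w_j, w_k = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        w_out = rng.normal(size=(3, 3))
        kernels = {
            "w_j": w_j.reshape(1, 1, 7, 3),
            "w_k": w_k.reshape(1, 1, 7, 3),
            "w_out": w_out.reshape(1, 1, 3, 3),
        }
        O_conv, H_conv = conv_jkff_step(x, h, kernels)
        O_dense, H_dense = jkff_step(
            x.reshape(1, 4), h.reshape(1, 3), w_j, w_k, w_out
        )
        assert np.allclose(O_conv.data.reshape(1, 3), O_dense.data, atol=1e-7)
        assert np.allclose(H_conv.data.reshape(1, 3), H_dense.data, atol=1e-7)

    def test_per_site_equivalence_with_shared_kernels(self, rng):
        """1x1-gate conv flip-flop equals the dense update applied at every
        spatial site with shared weights."""
        x = rng.normal(size=(1, 6, 6, 2))
        h = rng.random((1, 6, 6, 3))
        w_j, w_k = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        w_out = rng.normal(size=(3, 3))
        kernels = {
            "w_j": w_j.reshape(1, 1, 5, 3),
            "w_k": w_k.reshape(1, 1, 5, 3),
            "w_out": w_out.reshape(1, 1, 3, 3),
        }
        _, H_conv = conv_jkff_step(x, h, kernels)
        for i in range(6):
            for j in range(6):
                _, H_site = jkff_step(
                    x[:, i, j, :], h[:, i, j, :], w_j, w_k, w_out
                )
                assert np.allclose(H_conv.data[0, i, j], H_site.data[0], atol=1e-7)

    def test_ones_init_first_update(self, rng):
        """From the all-ones initial state, H_1 = 1 - K elementwise."""
        from scipy.special import expit

        x = rng.normal(size=(1, 4, 4, 2))
        h = np.ones((1, 4, 4, 3))
        kj = rng.normal(size=(3, 3, 5, 3))
        kernels = {"w_j": kj, "w_k": rng.normal(size=(3, 3, 5, 3)),
                   "w_out": rng.normal(size=(1, 1, 3, 3))}
        _, H1 = conv_jkff_step(x, h, kernels)
        inp = np.concatenate([x, h], axis=-1)
        K = expit(conv2d(inp, kernels["w_k"]).data)
        assert np.allclose(H1.data, 1.0 - K, atol=1e-6)


class TestXavierInit:
    def test_moments(self):
        w = xavier_init(1024, 512, seed=0, shape=(200, 500))
        target_var = 2.0 / 1536.0
        assert abs(w.var() - target_var) / target_var < 0.05
        se = np.sqrt(target_var / w.size)
        assert abs(w.mean()) < 3 * se

    def test_seeded_determinism(self):
        assert np.array_equal(xavier_init(10, 10, seed=3), xavier_init(10, 10, seed=3))

    def test_bad_fans_rejected(self):
        with pytest.raises(ValueError):
            xavier_init(0, 10, seed=0)


class TestFusedBlocks:
    """The fused conv/LRN/ReLU/pool paths must equal primitive composition."""

    @pytest.mark.parametrize("seed", range(3))
    def test_conv_block_equals_composition(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2, 8, 8, 3))
        w = rng.normal(size=(3, 3, 3, 4))
        b = rng.normal(size=4)
        p = LRNParams()
        fused = conv_block(x, w, b, p)
        composed = maxpool(relu(lrn(conv2d(x, w, b), p)))
        assert np.allclose(fused.data, composed.data, atol=1e-12)

    def test_lrn_relu_pool_equals_composition(self, rng):
        x = rng.normal(size=(1, 6, 6, 5))
        p = LRNParams()
        assert np.allclose(
            lrn_relu_pool(x, p).data, maxpool(relu(lrn(x, p))).data, atol=1e-12
        )


def test_layer_forwards_deterministic(rng):
    x = rng.normal(size=(1, 8, 8, 3))
    w = rng.normal(size=(3, 3, 3, 4))
    b = rng.normal(size=4)
    assert np.array_equal(conv2d(x, w, b).data, conv2d(x, w, b).data)
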