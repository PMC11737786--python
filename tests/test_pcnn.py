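"""Network numerics: every op against a brute-force oracle, plus gradients."""

import numpy as np
import pytest

from emdpcnn.pcnn import (
    ArchConfig,
    activation,
    build_model,
    conv1d_forward,
    pool,
    predict,
    softmax,
)
from emdpcnn.training import _loss_and_backward


def conv_oracle(x, w, b, stride, padding):
    """Direct triple-loop cross-correlation (independent of the implementation)."""
    F, C, Q = w.shape
    if padding == "same":
        left = (Q - 1) // 2
        right = Q - 1 - left
        x = np.pad(x, [(0, 0), (left, right)])
    T = x.shape[1]
    T_out = (T - Q) // stride + 1
    y = np.zeros((F, T_out))
    for f in range(F):
        for t in range(T_out):
            acc = b[f]
            for c in range(C):
                for q in range(Q):
                    acc += w[f, c, q] * x[c, t * stride + q]
            y[f, t] = acc
    return y


class TestConv1d:
    def test_hand_computed_valid_convolution(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        w = np.array([[[1.0, 1.0]]])
        out = conv1d_forward(x, w, np.zeros(1), stride=1, padding="valid")
        assert np.allclose(out, [[3.0, 5.0, 7.0]])

    def test_single_tap_identity_kernel(self):
        x = np.random.default_rng(0).normal(size=(3, 15))
        w = np.zeros((3, 3, 1))
        for f in range(3):
            w[f, f, 0] = 1.0
        out = conv1d_forward(x, w, np.zeros(3), padding="valid")
        assert np.allclose(out, x)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        C = int(rng.integers(1, 4))
        T = int(rng.integers(8, 16))
        F = int(rng.integers(1, 5))
        Q = int(rng.integers(1, 6))
        stride = int(rng.integers(1, 3))
        padding = ["valid", "same"][int(rng.integers(2))]
        x = rng.normal(size=(C, T))
        w = rng.normal(size=(F, C, Q))
        b = rng.normal(size=F)
        got = conv1d_forward(x, w, b, stride=stride, padding=padding)
        want = conv_oracle(x, w, b, stride, padding)
        assert np.max(np.abs(got - want)) < 1e-12

    def test_same_padding_preserves_length_at_stride_one(self):
        x = np.random.default_rng(1).normal(size=(2, 33))
        w = np.random.default_rng(2).normal(size=(4, 2, 20))
        out = conv1d_forward(x, w, np.zeros(4), padding="same")
        assert out.shape == (4, 33)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conv1d_forward(np.zeros((2, 10)), np.zeros((1, 3, 2)), np.zeros(1))


class TestActivation:
    def test_reference_points(self):
        assert activation(np.array(0.0), "tanh") == 0.0
        assert activation(np.array(0.0), "sigmoid") == 0.5
        assert activation(np.array(-2.0), "relu") == 0.0

    def test_relu_is_idempotent(self):
        x = np.random.default_rng(3).normal(size=100)
        once = activation(x, "relu")
        assert np.array_equal(activation(once, "relu"), once)

    def test_tanh_algebraic_identity(self):
        x = np.random.default_rng(4).uniform(-3, 3, size=200)
        want = (np.exp(x) - np.exp(-x)) / (np.exp(x) + np.exp(-x))
        assert np.max(np.abs(activation(x, "tanh") - want)) < 1e-12

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            activation(np.zeros(3), "swish")


def pool_oracle(x, size, stride, kind):
    F, T = x.shape
    T_out = (T - size) // stride + 1
    out = np.zeros((F, T_out))
    for f in range(F):
        for t in range(T_out):
            win = x[f, t * stride : t * stride + size]
            out[f, t] = win.max() if kind == "max" else win.mean()
    return out


class TestPool:
    def test_hand_computed_max_and_avg(self):
        x = np.array([[1.0, 3.0, 2.0, 4.0]])
        assert np.allclose(pool(x, 2, 2, "max"), [[3.0, 4.0]])
        assert np.allclose(pool(x, 2, 2, "avg"), [[2.0, 3.0]])

    def test_constant_input_invariant(self):
        x = np.full((2, 12), 5.0)
        for kind in ("max", "avg"):
            assert np.allclose(pool(x, 3, 3, kind), 5.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F = int(rng.integers(1, 4))
        T = int(rng.integers(6, 20))
        size = int(rng.integers(1, 5))
        stride = int(rng.integers(1, 4))
        kind = ["max", "avg"][int(rng.integers(2))]
        x = rng.normal(size=(F, T))
        got = pool(x, size, stride, kind)
        assert np.max(np.abs(got - pool_oracle(x, size, stride, kind))) < 1e-12

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            pool(np.zeros((1, 4)), size=5)


class TestBuildModel:
    def test_stem_parameter_count_for_2a_shape(self):
        model = build_model((22, 500), 4)
        conv = model.stem[0]
        assert conv.w.size + conv.b.size == 32 * (20 * 22) + 32 == 14_112

    def test_stem_output_preserves_length(self):
        model = build_model((22, 500), 4)
        x = np.random.default_rng(0).normal(size=(1, 22, 500))
        h = model.stem[0].forward(x, train=False)
        assert h.shape == (1, 32, 500)

    def test_softmax_rows_sum_to_one(self):
        model = build_model((3, 100), 4)
        p = predict(model, np.random.default_rng(1).normal(size=(7, 3, 100)))
        assert p.shape == (7, 4)
        assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-9
        assert np.all((p >= 0) & (p <= 1))

    def test_invalid_arch_config_names_the_field(self):
        with pytest.raises(ValueError, match="pool_size"):
            ArchConfig(pool_size=0)
        with pytest.raises(ValueError, match="dropout"):
            ArchConfig(dropout=1.5)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            build_model((3, 100), 1)


@pytest.fixture(scope="module")
def small_model():
    arch = ArchConfig(stem_filters=4, stem_kernel=5, branch_filters=4,
                      branch_kernel=3, pool_size=2, pool_stride=2,
                      dense_units=8, dropout=0.5, seed=0)
    return build_model((3, 50), 2, arch)


class TestPredict:
    def test_inference_is_deterministic(self, small_model):
        x = np.random.default_rng(2).normal(size=(6, 3, 50))
        assert np.array_equal(predict(small_model, x), predict(small_model, x))

    def test_batch_independence(self, small_model):
        x = np.random.default_rng(3).normal(size=(6, 3, 50))
        full = predict(small_model, x)
        single = predict(small_model, x[2])
        assert np.max(np.abs(full[2] - single[0])) < 1e-6

    def test_shape_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            predict(small_model, np.zeros((1, 3, 49)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        arch = ArchConfig(stem_filters=3, stem_kernel=5, branch_filters=3,
                          branch_kernel=3, pool_size=2, pool_stride=2,
                          dense_units=6, dropout=0.0, seed=1)
        model = build_model((2, 20), 3, arch)
        rng = np.random.default_rng(2)
        # jitter all parameters off their init so no ReLU pre-activation sits
        # exactly on the kink (zero-init biases put flat-region conv outputs
        # at exactly 0, where central differences disagree with the
        # subgradient by construction)
        for p in model.parameters():
            p += 0.01 * rng.normal(size=p.shape)
        x = rng.normal(size=(4, 2, 20))
        y = rng.integers(0, 3, size=4)
        l2 = 1e-3
        _loss_and_backward(model, x, y, l2, train_mode=True)
        grads = [g.copy() for g in model.gradients()]
        check_rng = np.random.default_rng(3)
        n_checked = 0
        for p, g in zip(model.parameters(), grads):
            flat = p.ravel()
            for _ in range(2):
                j = int(check_rng.integers(flat.size))
                eps = 1e-6
                orig = flat[j]
                flat[j] = orig + eps
                lp = _loss_and_backward(model, x, y, l2, True)
                flat[j] = orig - eps
                lm = _loss_and_backward(model, x, y, l2, True)
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = g.ravel()[j]
                if max(abs(numeric), abs(analytic)) > 1e-6:
                    rel = abs(numeric - analytic) / max(abs(numeric), abs(analytic))
                    assert rel < 1e-4, f"param {j}: numeric {numeric} vs analytic {analytic}"
                else:  # both below finite-difference resolution
                    assert abs(numeric - analytic) < 1e-6
                n_checked += 1
        assert n_checked >= 10


class TestSerialization:
    def test_save_load_preserves_predictions(self, tmp_path):
        arch = ArchConfig(stem_filters=4, stem_kernel=5, branch_filters=4,
                          branch_kernel=3, pool_size=2, pool_stride=2,
                          dense_units=8, seed=5)
        model = build_model((3, 40), 2, arch)
        x = np.random.default_rng(6).normal(size=(4, 3, 40))
        before = predict(model, x)
        model.save(tmp_path / "model")
        from emdpcnn.pcnn import PCNNModel

        back = PCNNModel.load(tmp_path / "model")
        assert np.array_equal(predict(back, x), before)

    def test_architecture_document_lists_branches(self):
        model = build_model((3, 40), 2)
        doc = model.architecture()
        assert len(doc["branches"]) == 2
        kinds = [doc["branches"][i][-1]["kind"] for i in range(2)]
        assert kinds == ["maxpool", "avgpool"]


def test_softmax_shifts_are_invariant():
    z = np.random.default_rng(7).normal(size=(5, 4))
    assert np.allclose(softmax(z), softmax(z + 100.0))
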