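"""Gradient and loss correctness of the layer kit.

Analytic backward passes are verified against central finite differences
(float32 arithmetic, so tolerances are a few 1e-2 relative); the loss
functions are verified against independent scalar-loop implementations.
"""

import math

import numpy as np
import pytest

from connectopred.nn import (
    Adam,
    BatchNorm1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    cross_entropy_loss,
    mae_loss,
    mae_with_grad,
    softmax,
    softmax_cross_entropy_with_grad,
)

RNG = np.random.default_rng(0)


def numeric_grad(f, x, eps=1e-2):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def check_input_grad(layer, x, train=True, atol=5e-3):
    """Compare layer.backward against finite differences of sum(output)."""
    y = layer.forward(x, train=train)
    dx = layer.backward(np.ones_like(y))
    num = numeric_grad(lambda: float(layer.forward(x, train=train).sum()), x)
    assert np.allclose(dx, num, atol=atol, rtol=5e-2), (
        f"max err {np.abs(dx - num).max()}"
    )


class TestLayerGradients:
    def test_conv2d_input_and_weight_gradients(self):
        rng = np.random.default_rng(1)
        layer = Conv2D(2, 3, rng)
        x = rng.standard_normal((2, 2, 5, 5)).astype(np.float32)
        check_input_grad(layer, x)
        # weight gradient
        layer.forward(x, train=True)
        for p in layer.params:
            p.grad[...] = 0.0
        layer.backward(np.ones((2, 3, 5, 5), dtype=np.float32))
        num = numeric_grad(
            lambda: float(layer.forward(x, train=True).sum()), layer.weight.value
        )
        assert np.allclose(layer.weight.grad, num, atol=5e-3, rtol=5e-2)

    def test_dense_gradients(self):
        rng = np.random.default_rng(2)
        layer = Dense(4, 3, rng)
        x = rng.standard_normal((5, 4)).astype(np.float32)
        check_input_grad(layer, x)
        layer.forward(x, train=True)
        for p in layer.params:
            p.grad[...] = 0.0
        layer.backward(np.ones((5, 3), dtype=np.float32))
        num = numeric_grad(
            lambda: float(layer.forward(x, train=True).sum()), layer.weight.value
        )
        assert np.allclose(layer.weight.grad, num, atol=5e-3, rtol=5e-2)

    def test_maxpool_routes_gradient_to_argmax(self):
        rng = np.random.default_rng(3)
        layer = MaxPool2D(2)
        x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
        y = layer.forward(x, train=True)
        dx = layer.backward(np.ones_like(y))
        # each 2x2 window routes exactly one unit of gradient
        assert dx.sum() == pytest.approx(y.size)
        assert set(np.unique(dx)) <= {0.0, 1.0}

    def test_batchnorm_training_gradient(self):
        rng = np.random.default_rng(4)
        layer = BatchNorm1D(4)
        layer.gamma.value[...] = rng.uniform(0.5, 1.5, 4)
        layer.beta.value[...] = rng.uniform(-0.5, 0.5, 4)
        x = rng.standard_normal((8, 4)).astype(np.float32)
        # weight the output sum so the gradient is not identically zero
        w = rng.standard_normal((8, 4)).astype(np.float32)
        y = layer.forward(x, train=True)
        dx = layer.backward(w)
        num = numeric_grad(lambda: float((layer.forward(x, train=True) * w).sum()), x)
        assert np.allclose(dx, num, atol=5e-3, rtol=5e-2)

    def test_batchnorm_inference_is_fixed_affine(self):
        rng = np.random.default_rng(5)
        layer = BatchNorm1D(4)
        layer.forward(rng.standard_normal((16, 4)).astype(np.float32), train=True)
        x = rng.standard_normal((3, 4)).astype(np.float32)
        y = layer.forward(x, train=False, cache=True)
        dx = layer.backward(np.ones_like(y))
        expected = np.tile(
            layer.gamma.value / np.sqrt(layer.running_var + layer.eps), (3, 1)
        )
        assert np.allclose(dx, expected, atol=1e-6)

    def test_relu_and_flatten_backward(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((3, 2, 4, 4)).astype(np.float32)
        net = Sequential([ReLU(), Flatten()])
        y = net.forward(x, train=True)
        dx = net.backward(np.ones_like(y))
        assert np.array_equal(dx, (x > 0).astype(np.float32))

    def test_dropout_scales_and_masks(self):
        layer = Dropout(0.5)
        layer.rng = np.random.default_rng(7)
        x = np.ones((200, 50), dtype=np.float32)
        y = layer.forward(x, train=True)
        assert set(np.unique(y)) == {0.0, 2.0}
        assert y.mean() == pytest.approx(1.0, abs=0.05)
        assert np.array_equal(layer.forward(x, train=False), x)

    def test_full_head_stack_gradient(self):
        rng = np.random.default_rng(8)
        net = Sequential([
            Conv2D(4, 3, rng), ReLU(), Flatten(),
            Dense(3 * 2 * 2, 5, rng), ReLU(), Dense(5, 2, rng),
        ])
        x = rng.standard_normal((3, 4, 2, 2)).astype(np.float32)
        y = np.array([0, 1, 1])

        def loss():
            out = net.forward(x, train=True)
            return softmax_cross_entropy_with_grad(out, y)[0]

        out = net.forward(x, train=True)
        _, grad = softmax_cross_entropy_with_grad(out, y)
        net.zero_grad()
        dx = net.backward(grad)
        num = numeric_grad(loss, x)
        assert np.allclose(dx, num, atol=5e-3, rtol=5e-2)


class TestLossOracles:
    def test_cross_entropy_matches_scalar_loop(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            p = rng.uniform(1e-6, 1 - 1e-6, n)
            y = rng.integers(0, 2, n)
            expected = -sum(
                yi * math.log(min(max(pi, 1e-7), 1 - 1e-7))
                + (1 - yi) * math.log(1 - min(max(pi, 1e-7), 1 - 1e-7))
                for pi, yi in zip(p, y)
            ) / n
            assert cross_entropy_loss(p, y) == pytest.approx(expected, abs=1e-12)

    def test_mae_matches_scalar_loop(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            yhat = rng.normal(100, 15, n)
            y = rng.normal(100, 15, n)
            expected = sum(abs(a - b) for a, b in zip(y, yhat)) / n
            assert mae_loss(yhat, y) == pytest.approx(expected, abs=1e-12)

    def test_cross_entropy_hand_examples(self):
        assert cross_entropy_loss([0.5], [1]) == pytest.approx(math.log(2), abs=1e-9)
        assert cross_entropy_loss([0.8, 0.2], [1, 0]) == pytest.approx(
            -0.5 * (math.log(0.8) + math.log(0.8)), abs=1e-9
        )
        # perfect predictions collapse to the clipping floor
        assert cross_entropy_loss([1.0, 0.0], [1, 0]) <= -math.log(1 - 1e-7) + 1e-12

    def test_mae_hand_examples(self):
        assert mae_loss([95, 95], [100, 90]) == pytest.approx(5.0)
        assert mae_loss([100.0], [100.0]) == 0.0

    def test_mae_shift_bounded_by_triangle_inequality(self):
        rng = np.random.default_rng(11)
        y = rng.normal(100, 15, 50)
        yhat = rng.normal(100, 15, 50)
        base = mae_loss(yhat, y)
        for c in (-7.0, 0.5, 3.0):
            assert abs(mae_loss(yhat + c, y) - base) <= abs(c) + 1e-12

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss([], [])
        with pytest.raises(ValueError):
            mae_loss([], [])

    def test_softmax_ce_gradient_numeric(self):
        rng = np.random.default_rng(12)
        logits = rng.standard_normal((6, 2)).astype(np.float64)
        y = rng.integers(0, 2, 6)
        _, grad = softmax_cross_entropy_with_grad(logits, y)
        num = numeric_grad(
            lambda: softmax_cross_entropy_with_grad(logits, y)[0], logits, eps=1e-5
        )
        assert np.allclose(grad, num, atol=1e-6)

    def test_mae_gradient_is_scaled_sign(self):
        out = np.array([[101.0], [98.0]])
        y = np.array([100.0, 99.0])
        _, grad = mae_with_grad(out, y)
        assert np.allclose(grad[:, 0], [0.5, -0.5])


class TestOptimizer:
    def test_adam_is_deterministic_and_descends(self):
        def run():
            rng = np.random.default_rng(13)
            layer = Dense(3, 1, rng)
            x = rng.standard_normal((20, 3)).astype(np.float32)
            y = (x @ np.array([[1.0], [-2.0], [0.5]], dtype=np.float32))[:, 0]
            opt = Adam(layer.params, lr=0.05)
            losses = []
            for _ in range(50):
                out = layer.forward(x, train=True)
                resid = out[:, 0] - y
                losses.append(float((resid**2).mean()))
                layer.weight.grad[...] = 0.0
                layer.bias.grad[...] = 0.0
                layer.backward((2 * resid[:, None] / len(y)).astype(np.float32))
                opt.step()
            return losses, layer.weight.value.copy()

        losses1, w1 = run()
        losses2, w2 = run()
        assert losses1 == losses2
        assert np.array_equal(w1, w2)
        assert losses1[-1] < 0.1 * losses1[0]
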