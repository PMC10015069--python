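"""The NumPy CNN engine: convolution against a scipy oracle, pooling
semantics, and finite-difference gradient checks layer by layer."""

import numpy as np
import pytest
from scipy.signal import correlate

from swarmcount.nn import (Conv2d, GlobalAvgPool, Linear, MaxPool2x2, ReLU,
                           SGD, Sequential, Sigmoid)


def finite_difference_check(layer, x, rng, n_samples=6, eps=1e-6, tol=1e-5):
    """Compare analytic parameter/input gradients of sum(layer(x)*w) with
    central differences."""
    w = rng.normal(size=layer.forward(x).shape)  # random linear functional

    def value():
        return float((layer.forward(x) * w).sum())

    y = layer.forward(x)
    for p in layer.params():
        p.grad[...] = 0.0
    dx = layer.backward(w)

    # input gradient
    xf = x.ravel()
    for i in rng.choice(x.size, size=min(n_samples, x.size), replace=False):
        orig = xf[i]
        xf[i] = orig + eps
        up = value()
        xf[i] = orig - eps
        down = value()
        xf[i] = orig
        fd = (up - down) / (2 * eps)
        assert abs(fd - dx.ravel()[i]) < tol * max(1.0, abs(fd)), \
            f"input grad mismatch at {i}: fd={fd} an={dx.ravel()[i]}"

    # parameter gradients
    layer.forward(x)
    for p in layer.params():
        p.grad[...] = 0.0
    layer.backward(w)
    for p in layer.params():
        flat = p.value.ravel()
        for i in rng.choice(flat.size, size=min(n_samples, flat.size),
                            replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            up = value()
            flat[i] = orig - eps
            down = value()
            flat[i] = orig
            fd = (up - down) / (2 * eps)
            assert abs(fd - p.grad.ravel()[i]) < tol * max(1.0, abs(fd)), \
                f"{p.name} grad mismatch at {i}: fd={fd} an={p.grad.ravel()[i]}"


class TestConv2d:
    @pytest.mark.parametrize("kernel", [1, 3, 5, 7])
    def test_matches_scipy_correlate(self, kernel, rng):
        conv = Conv2d(2, 3, kernel, rng)
        x = rng.normal(size=(2, 2, 9, 11))
        y = conv.forward(x)
        assert y.shape == (2, 3, 9, 11)
        w = conv.weight.value.reshape(3, 2, kernel, kernel)
        p = kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        for n in range(2):
            for o in range(3):
                expect = sum(
                    correlate(xp[n, c], w[o, c], mode="valid")
                    for c in range(2)) + conv.bias.value[o]
                assert np.abs(y[n, o] - expect).max() < 1e-10

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            Conv2d(1, 1, 2, rng)

    def test_gradients(self, rng):
        conv = Conv2d(2, 3, 3, rng)
        finite_difference_check(conv, rng.normal(size=(2, 2, 6, 7)), rng)


class TestMaxPool:
    def test_floor_semantics_and_values(self):
        x = np.arange(5 * 7, dtype=float).reshape(1, 1, 5, 7)
        y = MaxPool2x2().forward(x)
        assert y.shape == (1, 1, 2, 3)
        assert y[0, 0, 0, 0] == x[0, 0, 1, 1]  # max of each 2x2 block

    def test_gradient_routes_to_argmax_only(self, rng):
        pool = MaxPool2x2()
        x = rng.normal(size=(1, 2, 6, 6))
        y = pool.forward(x)
        g = np.ones_like(y)
        dx = pool.backward(g)
        assert dx.sum() == y.size  # one unit per pooled window
        assert ((dx != 0) <= np.isclose(
            x, np.repeat(np.repeat(y, 2, axis=2), 2, axis=3))).all()

    def test_gradients(self, rng):
        finite_difference_check(MaxPool2x2(), rng.normal(size=(2, 2, 6, 8)), rng)


@pytest.mark.parametrize("layer_factory", [
    lambda rng: ReLU(),
    lambda rng: Sigmoid(),
    lambda rng: GlobalAvgPool(),
], ids=["relu", "sigmoid", "gap"])
def test_activation_gradients(layer_factory, rng):
    layer = layer_factory(rng)
    finite_difference_check(layer, rng.normal(size=(2, 3, 5, 5)), rng)


def test_linear_gradients(rng):
    lin = Linear(6, 4, rng)
    # adapt the 2-D interface to the checker's NCHW expectation
    class Wrap:
        def params(self):
            return lin.params()

        def forward(self, x):
            return lin.forward(x.reshape(2, 6)).reshape(2, 4, 1, 1)

        def backward(self, g):
            return lin.backward(g.reshape(2, 4)).reshape(2, 6, 1, 1)

    finite_difference_check(Wrap(), rng.normal(size=(2, 6, 1, 1)), rng)


def test_sequential_composes_gradients(rng):
    net = Sequential([Conv2d(1, 2, 3, rng), ReLU(), MaxPool2x2(),
                      Conv2d(2, 1, 3, rng)])
    finite_difference_check(net, rng.normal(size=(1, 1, 8, 8)), rng)


class TestSGD:
    def test_momentum_and_weight_decay_update(self, rng):
        from swarmcount.nn import Param
        p = Param(np.array([1.0, -2.0]), "p")
        opt = SGD([p], lr=0.1, momentum=0.9, weight_decay=0.01)
        p.grad[:] = [0.5, 0.5]
        opt.step()
        # v = g + wd*w; w -= lr*v
        np.testing.assert_allclose(p.value, [1.0 - 0.1 * 0.51, -2.0 - 0.1 * 0.48])
        p.grad[:] = 0.0
        w_before = p.value.copy()
        opt.step()  # velocity persists under momentum
        expected_v = 0.9 * np.array([0.51, 0.48]) + 0.01 * w_before
        np.testing.assert_allclose(p.value, w_before - 0.1 * expected_v)

    def test_rejects_nonpositive_lr(self):
        with pytest.raises(ValueError):
            SGD([], lr=0.0)
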