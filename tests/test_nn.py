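"""Layer engine: convolution against an independent scipy oracle,
residual-block algebra, pooling gradients and full-network gradient
correctness by finite differences."""

import numpy as np
import pytest
from scipy import signal

from libsid import models, nn


def _naive_conv1d(x, w, stride, pad):
    """Independent reference: scipy correlate per (in, out) channel.

    x: (N, L, Cin); w: (k, Cin, Cout) -> (N, Lout, Cout)
    """
    N, L, Cin = x.shape
    k, _, Cout = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    Lout = (L + 2 * pad - k) // stride + 1
    out = np.zeros((N, Lout, Cout))
    for n in range(N):
        for co in range(Cout):
            acc = np.zeros(L + 2 * pad - k + 1)
            for ci in range(Cin):
                acc += signal.correlate(xp[n, :, ci], w[:, ci, co],
                                        mode="valid")
            out[n, :, co] = acc[::stride][:Lout]
    return out


def _naive_conv2d(x, w, stride, pad):
    N, H, W_, Cin = x.shape
    kh, kw, _, Cout = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    Hout = (H + 2 * pad - kh) // stride + 1
    Wout = (W_ + 2 * pad - kw) // stride + 1
    out = np.zeros((N, Hout, Wout, Cout))
    for n in range(N):
        for co in range(Cout):
            acc = np.zeros((xp.shape[1] - kh + 1, xp.shape[2] - kw + 1))
            for ci in range(Cin):
                acc += signal.correlate2d(xp[n, :, :, ci], w[:, :, ci, co],
                                          mode="valid")
            out[n, :, :, co] = acc[::stride, ::stride][:Hout, :Wout]
    return out


class TestConvOracle:
    @pytest.mark.parametrize("stride,pad", [(1, 1), (2, 3), (1, 0)])
    def test_conv1d_matches_scipy(self, stride, pad):
        rng = np.random.default_rng(0)
        conv = nn.Conv(3, 5, (7,), stride, pad, rng, np.float64)
        x = rng.normal(size=(2, 20, 3))
        got = conv.forward(x)
        want = _naive_conv1d(x, conv.weight.value, stride, pad)
        assert np.allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("stride,pad", [(1, 1), (2, 1)])
    def test_conv2d_matches_scipy(self, stride, pad):
        rng = np.random.default_rng(1)
        conv = nn.Conv(2, 4, (3, 3), stride, pad, rng, np.float64)
        x = rng.normal(size=(2, 6, 11, 2))
        got = conv.forward(x)
        want = _naive_conv2d(x, conv.weight.value, stride, pad)
        assert np.allclose(got, want, atol=1e-10)


class TestResidualBlockAlgebra:
    def _block(self, cin=4, cout=4, w=None):
        rng = np.random.default_rng(2)
        coeff = None if w is None else nn.Parameter(np.asarray(float(w)))
        return nn.ResidualBlock(cin, cout, 1, rng, coeff, np.float64)

    def test_zero_conv_path_gives_relu_of_input(self):
        """With F(x) = 0 and W = 1 the block reduces to ReLU(x)."""
        b = self._block(w=1.0)
        b.conv1.weight.value[...] = 0.0
        b.conv2.weight.value[...] = 0.0
        # make BN2 the identity on its (all-zero) input
        b.bn2.running_mean[...] = 0.0
        b.bn2.running_var[...] = 1.0 - b.bn2.eps
        x = np.random.default_rng(3).normal(size=(2, 10, 4))
        y = b.forward(x, train=False)
        assert np.allclose(y, np.maximum(x, 0.0), atol=1e-6)

    def test_w_zero_removes_shortcut(self):
        b = self._block(w=0.0)
        x = np.random.default_rng(4).normal(size=(2, 10, 4))
        y = b.forward(x, train=False)
        h = b.relu1.forward(b.bn1.forward(b.conv1.forward(x), False))
        f = b.bn2.forward(b.conv2.forward(h), False)
        assert np.allclose(y, np.maximum(f, 0.0))

    def test_matches_independent_reference(self):
        """W=1 block equals a from-scratch reference computation."""
        b = self._block(w=1.0)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 12, 4))
        got = models.residual_block_forward(x, b, train=False)

        def bn_eval(z, bn):
            zh = (z - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
            return bn.gamma.value * zh + bn.beta.value

        h = _naive_conv1d(x, b.conv1.weight.value, 1, 1)
        h = np.maximum(bn_eval(h, b.bn1), 0.0)
        f = bn_eval(_naive_conv1d(h, b.conv2.weight.value, 1, 1), b.bn2)
        want = np.maximum(f + x, 0.0)
        assert np.allclose(got, want, atol=1e-8)

    def test_projection_on_channel_change(self):
        b = self._block(cin=4, cout=8, w=1.0)
        x = np.random.default_rng(6).normal(size=(2, 10, 4))
        assert b.forward(x, train=False).shape == (2, 10, 8)
        assert b.shortcut is not None
        assert b.shortcut.weight.value.shape == (1, 4, 8)


def _network_loss(net, x, y):
    logits = net.forward(x, train=True)
    return nn.cross_entropy(logits, y)[0]


class TestGradients:
    """Analytic gradients vs central finite differences (float64)."""

    @pytest.mark.parametrize("mode", [models.PropagationMode.PER_BLOCK,
                                      models.PropagationMode.SHARED])
    def test_propagation_coefficient_gradients(self, mode):
        spec = models.NetworkSpec(dims=1, input_length=64, stem_channels=8,
                                  block_channels=(8, 16), n_classes=4,
                                  mode=mode, dtype="float64")
        net = models.build_network(spec, rng_seed=3)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 64))
        y = rng.integers(0, 4, 6)
        net.zero_grad()
        logits = net.forward(x, train=True)
        _, d = nn.cross_entropy(logits, y)
        net.backward(d)
        for p in net._w_params:
            analytic = float(p.grad)
            h = 1e-3
            old = float(p.value)
            p.value[...] = old + h
            lp = _network_loss(net, x, y)
            p.value[...] = old - h
            lm = _network_loss(net, x, y)
            p.value[...] = old
            fd = (lp - lm) / (2 * h)
            assert abs(fd - analytic) <= 1e-3 * max(abs(fd), abs(analytic))

    def test_all_parameter_gradients(self, tiny_net_spec):
        net = models.build_network(tiny_net_spec, rng_seed=3)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 64))
        y = rng.integers(0, 4, 5)
        net.zero_grad()
        logits = net.forward(x, train=True)
        _, d = nn.cross_entropy(logits, y)
        net.backward(d)
        check_rng = np.random.default_rng(0)
        for p in net.parameters:
            flat = p.value.reshape(-1)
            grad = p.grad.reshape(-1)
            n_check = min(3, flat.size)
            for i in check_rng.choice(flat.size, n_check, replace=False):
                h = 1e-5
                old = flat[i]
                flat[i] = old + h
                lp = _network_loss(net, x, y)
                flat[i] = old - h
                lm = _network_loss(net, x, y)
                flat[i] = old
                fd = (lp - lm) / (2 * h)
                assert abs(fd - grad[i]) <= 1e-4 * max(abs(fd), abs(grad[i]),
                                                       1e-4), p.name

    def test_input_gradient(self, tiny_net_spec):
        """Backprop to the input matches finite differences (the path
        saliency maps rely on)."""
        net = models.build_network(tiny_net_spec, rng_seed=3)
        rng = np.random.default_rng(7)
        x = rng.normal(size=(2, 64))
        y = np.array([1, 2])
        net.zero_grad()
        logits = net.forward(x, train=True)
        _, d = nn.cross_entropy(logits, y)
        dx = net.backward(d)
        for (n, i) in [(0, 5), (1, 40), (0, 63)]:
            h = 1e-5
            old = x[n, i]
            x[n, i] = old + h
            lp = _network_loss(net, x, y)
            x[n, i] = old - h
            lm = _network_loss(net, x, y)
            x[n, i] = old
            fd = (lp - lm) / (2 * h)
            assert abs(fd - dx[n, i]) <= 1e-4 * max(abs(fd), abs(dx[n, i]),
                                                    1e-4)


class TestPooling:
    def test_maxpool_forward_simple(self):
        pool = nn.MaxPool((3,), (2,), (1,))
        x = np.arange(8.0).reshape(1, 8, 1)
        out = pool.forward(x)
        assert list(out[0, :, 0]) == [1, 3, 5, 7]

    def test_maxpool_gradient_routes_to_argmax(self):
        pool = nn.MaxPool((3,), (2,), (1,))
        x = np.array([[3.0, 1.0, 2.0, 5.0, 0.0]]).reshape(1, 5, 1)
        out = pool.forward(x)
        dout = np.ones_like(out)
        dx = pool.backward(dout)[0, :, 0]
        # windows: [-,3,1] -> 3; [1,2,5] -> 5; [5,0,-] -> 5
        assert list(dx) == [1.0, 0.0, 0.0, 2.0, 0.0]

    def test_gap_backward_uniform(self):
        gap = nn.GlobalAvgPool()
        x = np.random.default_rng(0).normal(size=(2, 4, 3))
        out = gap.forward(x)
        dx = gap.backward(np.ones_like(out))
        assert np.allclose(dx, 0.25)
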