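"""Autodiff engine: every hand-written backward pass against central
finite differences, plus the pooling/unpooling contracts."""

import numpy as np
import pytest

from vesselseg import nn


def finite_diff(param_data, f, eps=1e-6):
    """Central-difference gradient of scalar f() w.r.t. the array in place."""
    g = np.zeros_like(param_data)
    it = np.nditer(param_data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = param_data[i]
        param_data[i] = old + eps
        hi = f()
        param_data[i] = old - eps
        lo = f()
        param_data[i] = old
        g[i] = (hi - lo) / (2 * eps)
    return g


def assert_grad_matches(tensors, f, rtol=1e-4):
    for t in tensors:
        t.zero_grad()
    loss = f()
    loss.backward()
    for t in tensors:
        num = finite_diff(t.data, lambda: float(f()))
        scale = max(np.abs(num).max(), 1e-8)
        assert np.abs(t.grad - num).max() / scale < rtol


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestElementwiseGrads:
    def test_arith_chain(self, rng):
        a = nn.Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = nn.Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        assert_grad_matches([a, b], lambda: ((a * b + a - 2.0 * b) ** 2).mean())

    def test_broadcast_add(self, rng):
        a = nn.Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
        b = nn.Tensor(rng.normal(size=(1, 3, 1)), requires_grad=True)
        assert_grad_matches([a, b], lambda: ((a + b) ** 2).sum())

    def test_relu_and_log(self, rng):
        a = nn.Tensor(np.abs(rng.normal(size=(5, 5))) + 0.1, requires_grad=True)
        assert_grad_matches([a], lambda: nn.log(nn.relu(a), clamp=1e-12).sum())


class TestLayerGrads:
    def test_conv2d_3x3(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        w = nn.Parameter(rng.normal(size=(4, 3, 3, 3)))
        b = nn.Parameter(rng.normal(size=4))
        assert_grad_matches([x, w, b], lambda: (nn.conv2d(x, w, b, 1) ** 2).mean())

    def test_conv2d_1x1(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 4, 5, 5)), requires_grad=True)
        w = nn.Parameter(rng.normal(size=(2, 4, 1, 1)))
        assert_grad_matches([x, w], lambda: (nn.conv2d(x, w, None, 0) ** 2).sum())

    def test_conv_transpose(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        w = nn.Parameter(rng.normal(size=(3, 5, 2, 2)))
        b = nn.Parameter(rng.normal(size=5))
        assert_grad_matches([x, w, b], lambda: (nn.conv_transpose2x2(x, w, b) ** 2).mean())

    def test_batchnorm_training(self, rng):
        bn = nn.BatchNorm2d(3)
        x = nn.Tensor(rng.normal(size=(4, 3, 5, 5)), requires_grad=True)
        t = rng.normal(size=(4, 3, 5, 5))  # target breaks BN's scale invariance

        def f():
            bn.running_mean[:] = 0  # keep f() side-effect free for the FD loop
            bn.running_var[:] = 1
            return ((bn(x) - t) ** 2).mean()

        assert_grad_matches([x, bn.gamma, bn.beta], f)

    def test_batchnorm_eval(self, rng):
        bn = nn.BatchNorm2d(3)
        bn.running_mean = rng.normal(size=3)
        bn.running_var = np.abs(rng.normal(size=3)) + 0.5
        bn.eval()
        x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        assert_grad_matches([x, bn.gamma, bn.beta], lambda: (bn(x) ** 2).mean())

    def test_softmax_channels(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        t = rng.normal(size=(2, 3, 4, 4))
        assert_grad_matches([x], lambda: ((nn.softmax_channels(x) - t) ** 2).sum())

    def test_concat(self, rng):
        a = nn.Tensor(rng.normal(size=(1, 2, 3, 3)), requires_grad=True)
        b = nn.Tensor(rng.normal(size=(1, 4, 3, 3)), requires_grad=True)
        assert_grad_matches([a, b], lambda: (nn.concat([a, b], axis=1) ** 2).sum())

    def test_haar_ops(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 4, 4, 4)), requires_grad=True)
        assert_grad_matches([x], lambda: (nn.haar_down(x) ** 2).sum())
        assert_grad_matches([x], lambda: (nn.haar_up(x) ** 2).sum())

    def test_maxpool_grad(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 2, 6, 6)), requires_grad=True)
        assert_grad_matches([x], lambda: (nn.max_pool2x2(x)[0] ** 2).sum())


class TestPooling:
    def test_single_window_argmax(self):
        y, idx = nn.max_pool2x2(nn.Tensor([[[[1.0, 2.0], [3.0, 4.0]]]]))
        assert y.data[0, 0, 0, 0] == 4.0
        assert idx[0, 0, 0, 0] == 3  # bottom-right in row-major window order

    def test_tie_break_first_row_major(self):
        y, idx = nn.max_pool2x2(nn.Tensor(np.full((1, 1, 2, 2), 5.0)))
        assert y.data[0, 0, 0, 0] == 5.0
        assert idx[0, 0, 0, 0] == 0  # top-left

    def test_matches_brute_force_window_scan(self, rng):
        x = rng.normal(size=(1, 1, 8, 8))
        y, idx = nn.max_pool2x2(nn.Tensor(x))
        for r in range(4):
            for c in range(4):
                win = x[0, 0, 2 * r : 2 * r + 2, 2 * c : 2 * c + 2]
                assert y.data[0, 0, r, c] == win.max()
                flat = int(idx[0, 0, r, c])
                assert win.reshape(4)[flat] == win.max()

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError, match="even"):
            nn.max_pool2x2(nn.Tensor(np.zeros((1, 1, 3, 4))))

    def test_unpool_places_maxima_zeros_elsewhere(self):
        x = nn.Tensor([[[[1.0, 2.0], [3.0, 4.0]]]])
        y, idx = nn.max_pool2x2(x)
        up = nn.max_unpool2x2(y, idx)
        assert np.array_equal(up.data, [[[[0.0, 0.0], [0.0, 4.0]]]])

    def test_unpool_sparsity_and_zero(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 8, 8)))
        y, idx = nn.max_pool2x2(x)
        up = nn.max_unpool2x2(y, idx)
        assert np.count_nonzero(up.data) <= y.data.size
        z = nn.max_unpool2x2(nn.Tensor(np.zeros_like(y.data)), idx)
        assert not np.any(z.data)

    def test_unpool_round_trip_restores_maxima(self, rng):
        """For any x: unpooling the pooled map puts each window max back at
        its recorded position and zeroes the rest of the window."""
        x = rng.normal(size=(2, 2, 8, 8))
        y, idx = nn.max_pool2x2(nn.Tensor(x))
        up = nn.max_unpool2x2(y, idx).data
        v = up.reshape(2, 2, 4, 2, 4, 2).transpose(0, 1, 2, 4, 3, 5).reshape(2, 2, 4, 4, 4)
        restored = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        assert np.array_equal(restored, y.data)
        assert np.all(np.count_nonzero(v, axis=-1) <= 1)

    def test_index_validation(self):
        with pytest.raises(ValueError, match="window"):
            nn.max_unpool2x2(nn.Tensor(np.ones((1, 1, 2, 2))), np.full((1, 1, 2, 2), 5))
        with pytest.raises(ValueError, match="shape"):
            nn.max_unpool2x2(nn.Tensor(np.ones((1, 1, 2, 2))), np.zeros((1, 1, 3, 2), int))


class TestOptimAndModule:
    def test_adam_minimises_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(400):
            opt.zero_grad()
            ((p * p).sum()).backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-3

    def test_no_grad_suppresses_tape(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        w = nn.Parameter(rng.normal(size=(2, 2, 3, 3)))
        with nn.no_grad():
            y = nn.conv2d(x, w, None, 1)
        assert y._parents == () and not y.requires_grad

    def test_state_dict_round_trip(self, rng):
        bn = nn.BatchNorm2d(4)
        bn.running_mean = rng.normal(size=4)
        state = bn.state_dict()
        bn2 = nn.BatchNorm2d(4)
        bn2.load_state_dict(state)
        assert np.allclose(bn2.running_mean, bn.running_mean)
        assert np.allclose(bn2.gamma.data, bn.gamma.data)
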