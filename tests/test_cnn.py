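"""Network building blocks, architecture contracts and training behavior."""

import numpy as np
import pytest

from quanvnet.cnn.layers import BatchNorm3d, Conv3d, MaxPool3d, _conv_reference
from quanvnet.cnn.model import (
    AffinityCNN,
    AffinityNetwork,
    NetworkConfig,
    build_network,
)
from quanvnet.metrics import evaluate_metrics


class TestConv3d:
    def test_matches_windowed_einsum_reference(self):
        rng = np.random.default_rng(0)
        conv = Conv3d(3, 5, 3, rng)
        x = rng.normal(size=(2, 3, 8, 8, 8)).astype(np.float32)
        out = conv.forward(x, train=False)
        ref = _conv_reference(x, conv.W, conv.b)
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_gradients_match_direct_space_formulas(self):
        rng = np.random.default_rng(1)
        conv = Conv3d(4, 4, 3, rng)
        x = rng.normal(size=(2, 4, 6, 6, 6)).astype(np.float32)
        out = conv.forward(x, train=True)
        dy = rng.normal(size=out.shape).astype(np.float32)
        dx = conv.backward(dy)
        # weight gradient: windowed einsum oracle
        from numpy.lib.stride_tricks import sliding_window_view
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
        dW_ref = np.einsum("bcdhwxyz,bodhw->ocxyz", win, dy, optimize=True)
        np.testing.assert_allclose(conv.dW, dW_ref, rtol=1e-3, atol=1e-4)
        # input gradient: full correlation with flipped transposed kernel
        wback = np.ascontiguousarray(
            conv.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        dx_ref = _conv_reference(dy, wback, np.zeros(4, np.float32))
        np.testing.assert_allclose(dx, dx_ref, atol=1e-4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            Conv3d(2, 2, 4, np.random.default_rng(0))


def test_maxpool_gradient_routes_to_maxima():
    rng = np.random.default_rng(0)
    pool = MaxPool3d()
    x = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
    out = pool.forward(x, train=True)
    dy = np.ones_like(out)
    dx = pool.backward(dy)
    assert dx.sum() == pytest.approx(out.size)
    # gradient lands only on argmax voxels
    assert ((dx != 0) <= (x == np.repeat(np.repeat(np.repeat(
        out, 2, 2), 2, 3), 2, 4))).all()


def test_batchnorm_normalizes_batch():
    rng = np.random.default_rng(0)
    bn = BatchNorm3d(3)
    x = (rng.normal(size=(4, 3, 4, 4, 4)) * 5 + 2).astype(np.float32)
    out = bn.forward(x, train=True)
    assert np.allclose(out.mean(axis=(0, 2, 3, 4)), 0.0, atol=1e-5)
    assert np.allclose(out.std(axis=(0, 2, 3, 4)), 1.0, atol=1e-3)


class TestNetworkStructure:
    def test_classical_layer_counts(self):
        net = build_network(NetworkConfig(), in_channels=19, grid_side=48)
        convs = [b for name, b in net.blocks.items()]
        assert len(convs) == 5
        assert net.fc1.W.shape[1] == 10 and net.fc2.W.shape[1] == 1

    def test_hybrid_channel_arithmetic(self):
        # 2*19 = 38 quantum channels + 26 conv filters restore width 64
        net = build_network(NetworkConfig(variant="hybrid"), in_channels=19,
                            grid_side=48)
        assert net.blocks["conv1"].conv.out_ch == 64 - 38

    def test_hybrid_width_overflow_rejected(self):
        cfg = NetworkConfig.scaled("hybrid")  # first width 16
        with pytest.raises(ValueError):
            build_network(cfg, in_channels=19, grid_side=48)  # 38 > 16

    def test_parameter_count_ordering_full_config(self):
        counts = {
            v: build_network(NetworkConfig(variant=v), in_channels=19,
                             grid_side=48).parameter_count()
            for v in ("classical", "hybrid", "downsized")
        }
        assert counts["downsized"] < counts["hybrid"] < counts["classical"]

    def test_variants_same_prediction_shape(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 8, 8, 8)).astype(np.float32)
        xq = rng.normal(size=(2, 6, 8, 8, 8)).astype(np.float32)
        cfg = dict(conv_filters=(8, 8, 8, 8, 8), conv_kernels=(3, 3, 3, 3, 3))
        for variant in ("classical", "hybrid", "downsized"):
            net = AffinityNetwork(NetworkConfig(variant=variant, **cfg), 3, 8)
            out = net.forward(x, xq if variant == "hybrid" else None)
            assert out.shape == (2,)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(conv_filters=(8, 16, 8, 8, 8))
        with pytest.raises(ValueError):
            NetworkConfig(fc_sizes=(10, 2))
        with pytest.raises(ValueError):
            NetworkConfig(variant="quantum")


class TestBackprop:
    def test_numeric_gradient_small_eps(self):
        """Analytic gradients agree with central differences as eps -> 0."""
        cfg = NetworkConfig(conv_filters=(4, 4, 4, 4, 4),
                            conv_kernels=(3, 3, 3, 3, 3))
        net = AffinityNetwork(cfg, in_channels=2, grid_side=8, seed=0)
        rng = np.random.default_rng(0)
        # the output layer starts at zero; give it weight so gradients flow
        net.fc2.W[...] = rng.normal(0, 0.5, net.fc2.W.shape).astype(np.float32)
        x = rng.normal(size=(2, 2, 8, 8, 8)).astype(np.float32)
        y = rng.normal(size=2)

        def loss():
            pred = net.forward(x, train=True)
            return float(((pred - y) ** 2).mean()), pred

        _, pred = loss()
        net.backward((2 * (pred - y) / len(y)).astype(np.float32))
        checked = 0
        for name, p, g in net.params():
            if name == "b":   # conv bias is absorbed by batch norm (grad 0)
                continue
            idx = tuple(0 for _ in p.shape)
            eps, old = 1e-3, p[idx]
            p[idx] = old + eps
            l1, _ = loss()
            p[idx] = old - eps
            l2, _ = loss()
            p[idx] = old
            num = (l1 - l2) / (2 * eps)
            assert abs(num - g[idx]) < 0.05 * max(abs(num), abs(g[idx]), 0.1), \
                f"{name}: analytic {g[idx]}, numeric {num}"
            checked += 1
        assert checked >= 12


class TestTraining:
    @staticmethod
    def _toy_data(n=24, c=2, side=8, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, c, side, side, side)).astype(np.float32) * 0.1
        # affinity signal: total mass of channel 0
        bump = rng.random(n).astype(np.float32) * 2
        X[:, 0] += bump[:, None, None, None] / 10
        y = 2.0 + bump * 2
        return X, y

    @staticmethod
    def _cfg(**kw):
        return NetworkConfig(conv_filters=(6, 6, 6, 6, 6),
                             conv_kernels=(3, 3, 3, 3, 3), lr=1e-3, **kw)

    def test_constant_labels_learn_constant(self):
        X, _ = self._toy_data()
        y = np.full(len(X), 4.2)
        model = AffinityCNN(X[:16], y[:16], X[16:], y[16:], self._cfg())
        with pytest.warns(UserWarning):
            res = model.fit(seed=0, epochs=3)
        assert res.history.iloc[-1].rmse < 0.5
        assert np.allclose(res.predict(X[16:]), 4.2, atol=1.0)

    def test_loss_decreases_on_learnable_signal(self):
        X, y = self._toy_data(n=32)
        model = AffinityCNN(X[:24], y[:24], X[24:], y[24:], self._cfg())
        res = model.fit(seed=1, epochs=5)
        losses = res.history.train_loss.to_numpy()
        assert losses[-1] < losses[0]

    def test_same_seed_same_first_epoch(self):
        X, y = self._toy_data()
        kwargs = dict(epochs=1)
        m = AffinityCNN(X[:16], y[:16], X[16:], y[16:], self._cfg())
        l1 = m.fit(seed=3, **kwargs).history.train_loss[0]
        l2 = m.fit(seed=3, **kwargs).history.train_loss[0]
        assert l1 == l2

    def test_empty_sets_rejected(self):
        X, y = self._toy_data()
        with pytest.raises(ValueError):
            AffinityCNN(X[:0], y[:0], X, y, self._cfg())


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate_metrics(y, y)
        assert (m.rmse, m.mae, m.r2, m.pearson, m.spearman) == (0, 0, 1, 1, 1)

    def test_anticorrelated(self):
        y = np.array([-2.0, -1.0, 1.0, 2.0])
        m = evaluate_metrics(y, -y)
        assert m.pearson == pytest.approx(-1.0)
        assert m.spearman == pytest.approx(-1.0)

    def test_hand_computed_oracle(self):
        y = np.array([1.0, 2.0, 4.0])
        yhat = np.array([1.5, 1.5, 5.0])
        m = evaluate_metrics(y, yhat)
        err = yhat - y
        assert m.rmse == pytest.approx(np.sqrt((err**2).mean()), abs=1e-12)
        assert m.mae == pytest.approx(np.abs(err).mean(), abs=1e-12)
        ss_res = (err**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert m.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        cov = np.mean((y - y.mean()) * (yhat - yhat.mean()))
        pearson = cov / (y.std() * yhat.std())
        assert m.pearson == pytest.approx(pearson, abs=1e-12)
        # ranks: y -> 1,2,3 ; yhat -> 1.5,1.5,3 (average ranks on ties)
        r1, r2 = np.array([1, 2, 3.0]), np.array([1.5, 1.5, 3.0])
        cov_r = np.mean((r1 - r1.mean()) * (r2 - r2.mean()))
        spear = cov_r / (r1.std() * r2.std())
        assert m.spearman == pytest.approx(spear, abs=1e-12)

    def test_zero_variance_targets_warn(self):
        with pytest.warns(UserWarning):
            m = evaluate_metrics(np.ones(5), np.arange(5.0))
        assert np.isnan(m.pearson)
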