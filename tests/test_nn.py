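"""Backend checks: analytic gradients vs finite differences, loss values,
training-loop determinism."""

import numpy as np
import pytest

from endoscreen import nn


def _num_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def _check_layer(layer, x_shape, seed=0, tol=5e-3):
    """Compare backward() against finite differences of sum(w * forward)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(x_shape).astype(np.float32)
    w = rng.standard_normal(layer.forward(x, train=True).shape).astype(np.float32)

    def loss():
        return float((layer.forward(x, train=True) * w).sum())

    loss()
    dx = layer.backward(w)
    ndx = _num_grad(loss, x)
    scale = np.abs(ndx).max() + 1e-8
    assert np.abs(dx - ndx).max() / scale < tol
    loss()
    layer.backward(w)
    for p in layer.params():
        analytic = p.grad.copy()
        numeric = _num_grad(loss, p.data)
        scale = np.abs(numeric).max() + 1e-8
        assert np.abs(analytic - numeric).max() / scale < tol, p.name


@pytest.mark.parametrize("layer_fn,x_shape", [
    (lambda r: nn.Conv2d(3, 4, 3, rng=r), (2, 3, 6, 6)),
    (lambda r: nn.Conv2d(4, 6, 3, stride=2, groups=2, rng=r), (2, 4, 7, 7)),
    (lambda r: nn.Conv2d(4, 8, 3, groups=4, rng=r), (2, 4, 5, 5)),
    (lambda r: nn.BatchNorm2d(3), (4, 3, 5, 5)),
    (lambda r: nn.MaxPool2d(2), (2, 3, 6, 6)),
    (lambda r: nn.MaxPool2d(3, 2, padding=1), (2, 3, 7, 7)),
    (lambda r: nn.Linear(5, 3, rng=r), (4, 5)),
    (lambda r: nn.GlobalAvgPool(), (2, 3, 4, 4)),
    (lambda r: nn.UpsampleNearest2(), (2, 3, 3, 3)),
    (lambda r: nn.SEBlock(8, rng=r), (2, 8, 4, 4)),
    (lambda r: nn.GhostModule(3, 8, rng=r), (2, 3, 6, 6)),
], ids=["conv", "grouped_strided_conv", "depthwise_conv", "batchnorm",
        "maxpool2", "maxpool3s2", "linear", "gap", "upsample", "se", "ghost"])
def test_layer_gradients_match_finite_differences(layer_fn, x_shape):
    _check_layer(layer_fn(np.random.default_rng(1)), x_shape, tol=1e-2)


def test_unet_gradients_match_finite_differences():
    net = nn.UNet(in_channels=2, base_channels=2, depth=2,
                  rng=np.random.default_rng(0))
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 2, 8, 8)).astype(np.float32)
    w = rng.standard_normal((2, 1, 8, 8)).astype(np.float32)

    def loss():
        return float((net.forward(x, train=True) * w).sum())

    loss()
    dx = net.backward(w)
    # directional derivatives are robust to ReLU/max-pool kinks that make
    # single-coordinate finite differences noisy in float32
    for seed in range(3):
        v = np.random.default_rng(seed).standard_normal(x.shape) \
            .astype(np.float32)
        v /= np.linalg.norm(v)
        eps = 1e-3
        num = (((net.forward(x + eps * v, train=True) * w).sum()
                - (net.forward(x - eps * v, train=True) * w).sum())
               / (2 * eps))
        assert float((dx * v).sum()) == pytest.approx(float(num), rel=5e-2,
                                                      abs=5e-2)


class TestLosses:
    def test_cross_entropy_known_value_and_gradient_direction(self):
        logits = np.zeros((1, 2), dtype=np.float32)  # p = (0.5, 0.5)
        loss, d = nn.softmax_cross_entropy(logits, np.array([1]))
        assert loss == pytest.approx(np.log(2), abs=1e-6)
        assert d[0, 1] < 0 < d[0, 0]

    def test_focal_reduces_to_ce_at_gamma0_alpha1(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((8, 2)).astype(np.float32)
        labels = rng.integers(0, 2, size=8)
        l1, d1 = nn.softmax_cross_entropy(logits, labels)
        l2, d2 = nn.focal_cross_entropy(logits, labels, gamma=0, alpha=1)
        assert l1 == pytest.approx(l2, rel=1e-6)
        assert np.allclose(d1, d2, atol=1e-6)

    def test_focal_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((4, 2)).astype(np.float32)
        labels = np.array([0, 1, 1, 0])
        _, d = nn.focal_cross_entropy(logits, labels, gamma=2.0, alpha=0.25)
        eps = 1e-3
        for i, j in [(0, 0), (1, 1), (2, 0), (3, 1)]:
            old = logits[i, j]
            logits[i, j] = old + eps
            fp, _ = nn.focal_cross_entropy(logits, labels, 2.0, 0.25)
            logits[i, j] = old - eps
            fm, _ = nn.focal_cross_entropy(logits, labels, 2.0, 0.25)
            logits[i, j] = old
            assert d[i, j] == pytest.approx((fp - fm) / (2 * eps), abs=1e-4)

    def test_bce_dice_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((2, 1, 4, 4)).astype(np.float32)
        targets = (rng.random((2, 1, 4, 4)) > 0.5).astype(np.float32)
        _, d = nn.bce_dice(logits, targets)
        eps = 1e-3
        for idx in [(0, 0, 1, 2), (1, 0, 3, 3)]:
            old = logits[idx]
            logits[idx] = old + eps
            fp, _ = nn.bce_dice(logits, targets)
            logits[idx] = old - eps
            fm, _ = nn.bce_dice(logits, targets)
            logits[idx] = old
            assert d[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-4)


class TestTraining:
    def _toy_data(self):
        rng = np.random.default_rng(0)
        x = rng.random((64, 3, 8, 8), dtype=np.float32) * 0.3
        y = rng.integers(0, 2, size=64)
        x[y == 1, 1, 2:6, 2:6] += 0.6  # green centre patch marks positives
        return x, y.astype(np.int64)

    def _tiny_net(self, seed=0):
        rng = np.random.default_rng(seed)
        return nn.Sequential([
            nn.Conv2d(3, 4, 3, rng=rng), nn.ReLU(),
            nn.GlobalAvgPool(), nn.Linear(4, 2, rng=rng)])

    def test_fit_reduces_loss_and_learns(self):
        x, y = self._toy_data()
        net = self._tiny_net()
        hist = nn.fit(net, x, y, nn.softmax_cross_entropy, epochs=30,
                      batch_size=16, lr=1e-2, seed=0)
        assert hist[-1] < hist[0]
        preds = nn.predict_batched(net, x).argmax(axis=1)
        assert (preds == y).mean() > 0.9

    def test_fit_is_deterministic_in_seed(self):
        x, y = self._toy_data()
        h1 = nn.fit(self._tiny_net(1), x, y, nn.softmax_cross_entropy,
                    epochs=3, seed=5)
        h2 = nn.fit(self._tiny_net(1), x, y, nn.softmax_cross_entropy,
                    epochs=3, seed=5)
        assert h1 == h2
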