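"""Adam optimiser and seeded minibatch training loops."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, set_rng


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def predict_batched(model: Layer, x: np.ndarray, batch_size=64) -> np.ndarray:
    """Forward pass in inference mode, batched to bound memory."""
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(model.forward(x[i:i + batch_size], train=False))
    return np.concatenate(outs, axis=0)


def fit(model: Layer, x: np.ndarray, y: np.ndarray, loss_fn, *, epochs=5,
        batch_size=64, lr=1e-3, seed=0, shuffle=True, callback=None):
    """Train ``model`` on arrays ``x``/``y`` with ``loss_fn(out, yb)``.

    ``loss_fn`` returns (scalar, dout). Returns the per-epoch mean-loss
    history. Fully seeded: shuffling and dropout share one generator.
    """
    rng = np.random.default_rng(seed)
    set_rng(model, rng)
    opt = Adam(model.params(), lr=lr)
    n = len(x)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        total, seen = 0.0, 0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            out = model.forward(x[idx], train=True)
            loss, dout = loss_fn(out, y[idx])
            model.backward(dout)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / max(seen, 1))
        if callback is not None:
            callback(epoch, history[-1])
    return history
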