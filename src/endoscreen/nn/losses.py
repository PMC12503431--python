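"""Loss functions returning (scalar loss, gradient w.r.t. the model output)."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels, class_weights=None):
    """Mean cross entropy over a batch of integer labels.

    ``class_weights`` (one weight per class) rescales each sample's
    contribution — the usual prevalence correction for imbalanced data.
    """
    n = logits.shape[0]
    p = softmax(logits)
    pt = np.clip(p[np.arange(n), labels], _EPS, 1.0)
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    loss = float((-w * np.log(pt)).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(np.float32)


def focal_cross_entropy(logits, labels, gamma=2.0, alpha=0.25):
    """Binary focal cross entropy on 2-class softmax logits.

    Per sample: -alpha * (1 - p_t)^gamma * log(p_t), where p_t is the
    predicted probability of the true class; gamma=0, alpha=1 reduces to
    plain cross entropy.
    """
    n = logits.shape[0]
    p = softmax(logits)
    pt = np.clip(p[np.arange(n), labels], _EPS, 1.0)
    one_minus = 1.0 - pt
    loss = float((-alpha * one_minus ** gamma * np.log(pt)).mean())
    # dL/dpt, then chain through softmax: dpt/dz_j = pt*(delta_jy - p_j)
    if gamma == 0:
        dpt = -alpha / pt
    else:
        dpt = alpha * (gamma * one_minus ** (gamma - 1) * np.log(pt)
                       - one_minus ** gamma / pt)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), labels] = 1.0
    dlogits = (dpt * pt)[:, None] * (onehot - p)
    return loss, (dlogits / n).astype(np.float32)


def bce_dice(logits, targets, dice_weight=1.0):
    """Binary cross entropy plus soft-Dice loss for segmentation logits.

    ``logits``/``targets`` are (N, 1, H, W); the Dice term is computed per
    sample and averaged, so small and large masks contribute equally.
    """
    n = logits.shape[0]
    p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
    t = targets
    pc = np.clip(p, _EPS, 1 - _EPS)
    bce = float(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)).mean())
    dbce_dlogits = (p - t) / t.size  # sigmoid chain already folded in

    eps = 1.0
    axes = (1, 2, 3)
    inter = (p * t).sum(axis=axes)
    sums = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2 * inter + eps) / (sums + eps)
    dice_loss = float((1.0 - dice).mean())
    # d(1-dice_i)/dp_j = -(2*t_j*(sums+eps) - (2*inter+eps)) / (sums+eps)^2
    num = (2 * inter + eps)[:, None, None, None]
    den = (sums + eps)[:, None, None, None]
    ddice = -(2 * t * den - num) / den ** 2 / n

    dlogits = dbce_dlogits + dice_weight * ddice * p * (1 - p)
    return bce + dice_weight * dice_loss, dlogits.astype(np.float32)
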