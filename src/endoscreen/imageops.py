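"""Shared array-level image helpers (resizing, layout conversion)."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize


def downsample_batch(frames: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Resize (N, H, W, C) float frames to (N, h, w, C).

    Integer decimation factors use fast block averaging (an anti-aliased
    mean filter); anything else falls back to skimage resize.
    """
    frames = np.asarray(frames, dtype=np.float32)
    n, h, w, c = frames.shape
    th, tw = size
    if (h, w) == (th, tw):
        return frames
    if h % th == 0 and w % tw == 0 and h // th == w // tw:
        f = h // th
        return frames.reshape(n, th, f, tw, f, c).mean(axis=(2, 4))
    out = np.empty((n, th, tw, c), dtype=np.float32)
    for i in range(n):
        out[i] = _sk_resize(frames[i], (th, tw), anti_aliasing=h > th,
                            preserve_range=True)
    return out


def to_nchw(frames: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> contiguous float32 (N, C, H, W)."""
    return np.ascontiguousarray(np.transpose(frames, (0, 3, 1, 2)),
                                dtype=np.float32)


def upsample_mask_nearest(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample of a 2-D binary mask to ``size``."""
    h, w = mask.shape
    th, tw = size
    rows = (np.arange(th) * h // th).clip(max=h - 1)
    cols = (np.arange(tw) * w // tw).clip(max=w - 1)
    return mask[np.ix_(rows, cols)]
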