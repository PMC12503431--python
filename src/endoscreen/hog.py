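"""Histogram-of-oriented-gradients similarity filtering (IQM stage 1).

Each frame is summarised by the canonical HOG descriptor (unsigned
orientation bins, magnitude weighting, per-block L2 normalisation) and
compared by cosine similarity to an operator-chosen index frame — the first
frame of relevance in the examination. Two thresholds act together:

* relevance: a frame is kept only if its similarity to the index frame is
  at least ``tau_rel`` (irrelevant / off-target content scores low);
* redundancy: a frame nearly identical to the most recently retained frame
  (similarity >= ``tau_dup``) is dropped as a near-duplicate.

Either check can be disabled (``tau_rel = -1`` / ``tau_dup >= 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import hog as _skimage_hog
from skimage.transform import resize as _resize

from .core_data import FrameRecord, VideoRecord


@dataclass
class HogParams:
    cell_size: int = 8
    block_size: int = 2
    n_bins: int = 9
    resize_to: tuple[int, int] = (224, 224)
    epsilon: float = 1e-6  # zero-norm guard for degenerate (flat) frames

    def __post_init__(self):
        if min(self.cell_size, self.block_size, self.n_bins) <= 0:
            raise ValueError("cell_size, block_size and n_bins must be positive")
        if any(s % self.cell_size for s in self.resize_to):
            raise ValueError("resize_to must be divisible by cell_size")

    @property
    def descriptor_length(self) -> int:
        cells = [s // self.cell_size for s in self.resize_to]
        blocks = [c - self.block_size + 1 for c in cells]
        return blocks[0] * blocks[1] * self.block_size ** 2 * self.n_bins


@dataclass
class HogDescriptor:
    values: np.ndarray

    def __len__(self):
        return len(self.values)


@dataclass
class FilterParams:
    index_frame: int = 0
    tau_rel: float = 0.5
    tau_dup: float = 0.98  # >= 1 disables the near-duplicate check

    def __post_init__(self):
        if not (-1 <= self.tau_rel <= 1):
            raise ValueError("tau_rel must lie in [-1, 1]")


def compute_hog(frame: FrameRecord | np.ndarray,
                params: HogParams | None = None) -> HogDescriptor:
    """Grayscale + resize + HOG; deterministic, all-zero on flat frames."""
    params = params or HogParams()
    pixels = frame.pixels if isinstance(frame, FrameRecord) else np.asarray(frame)
    gray = rgb2gray(pixels) if pixels.ndim == 3 else pixels.astype(np.float64)
    if gray.shape != tuple(params.resize_to):
        gray = _resize(gray, params.resize_to, anti_aliasing=True)
    desc = _skimage_hog(
        gray,
        orientations=params.n_bins,
        pixels_per_cell=(params.cell_size, params.cell_size),
        cells_per_block=(params.block_size, params.block_size),
        block_norm="L2",
        feature_vector=True,
    )
    return HogDescriptor(desc.astype(np.float64))


def cosine_similarity(a, b) -> float:
    """dot(a,b)/(|a||b|); returns 0.0 when either vector is all-zero."""
    va = a.values if isinstance(a, HogDescriptor) else np.asarray(a, dtype=np.float64)
    vb = b.values if isinstance(b, HogDescriptor) else np.asarray(b, dtype=np.float64)
    if va.shape != vb.shape:
        raise ValueError(f"descriptor lengths differ: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))


def hog_similarities(video: VideoRecord, hog: HogParams | None = None,
                     index_frame: int = 0) -> np.ndarray:
    """Cosine similarity of every frame to the index frame."""
    hog = hog or HogParams()
    descs = [compute_hog(f, hog) for f in video.frames]
    ref = descs[index_frame]
    return np.array([cosine_similarity(d, ref) for d in descs])


def similarity_filter(video: VideoRecord, hog: HogParams | None = None,
                      filt: FilterParams | None = None) -> list[int]:
    """Return the retained frame positions (strictly increasing).

    The index frame is always retained. A later frame survives iff its
    similarity to the index frame is >= tau_rel (relevance) and its
    similarity to the most recently retained frame is < tau_dup
    (non-redundancy). Frames before the index frame are discarded: the
    index frame marks the start of the relevant portion of the exam.
    """
    if not video.frames:
        raise ValueError("empty video")
    hog = hog or HogParams()
    filt = filt or FilterParams()
    if filt.index_frame >= len(video.frames):
        raise ValueError("index_frame beyond end of video")
    descs = [compute_hog(f, hog) for f in video.frames]
    ref = descs[filt.index_frame]
    retained = [filt.index_frame]
    for i in range(filt.index_frame + 1, len(video.frames)):
        if cosine_similarity(descs[i], ref) < filt.tau_rel:
            continue
        if filt.tau_dup < 1.0 and \
                cosine_similarity(descs[i], descs[retained[-1]]) >= filt.tau_dup:
            continue
        retained.append(i)
    return retained
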