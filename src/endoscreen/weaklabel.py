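"""Glottis segmentation and weak quality labelling (IQM stage 2a).

A U-Net is trained on segmentation pairs (benchmark-style image + binary
glottis mask) and then applied to unlabelled video frames. A frame is
weakly labelled *good* when the predicted glottis is entirely visible,
operationalised as two criteria on the thresholded predicted mask: a
minimum area and clearance from the frame border. Blurred or hazy frames
yield fragmented, low-confidence masks that fail these criteria; off-target
frames yield (nearly) empty masks.

The default network is deliberately small (depth 3, 8 base channels,
64x64 input) so that training 1000 pairs takes minutes on one CPU core;
masks are produced at the frame's native resolution by nearest-neighbour
upsampling of the thresholded prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core_data import FrameRecord, SegmentationMask, VideoRecord
from .imageops import downsample_batch, to_nchw, upsample_mask_nearest
from .metrics import dice

GOOD, POOR = "good", "poor"


@dataclass
class UNetSpec:
    depth: int = 3
    base_channels: int = 8
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if any(s % (2 ** self.depth) for s in self.input_size):
            raise ValueError("input_size must be divisible by 2^depth")


@dataclass
class TrainConfig:
    """U-Net training budget and abstention augmentation.

    ``degrade_fraction`` controls quality-abstention training: that fraction
    of extra samples are degraded copies (Gaussian blur plus secretion-like
    haze) of training frames paired with an *empty* target mask, teaching
    the network to abstain when the glottis is not resolvable — the
    property the downstream visibility criteria rely on.
    """

    epochs: int = 6
    learning_rate: float = 3e-3
    batch_size: int = 32
    seed: int = 0
    degrade_fraction: float = 0.5
    degrade_sigma_range: tuple[float, float] = (2.0, 6.0)
    haze_strength: float = 0.35
    haze_level: float = 0.85


@dataclass
class VisibilityCriteria:
    """Operational reading of 'the glottal area is entirely visible'."""

    min_area_fraction: float = 0.002
    border_margin: int = 2
    prob_threshold: float = 0.5

    def __post_init__(self):
        if self.min_area_fraction < 0 or self.min_area_fraction >= 1:
            raise ValueError("min_area_fraction must be in [0, 1)")
        if self.border_margin < 0:
            raise ValueError("border_margin must be >= 0")


class SegmentationModel:
    """Trained U-Net plus its input geometry."""

    def __init__(self, net: nn.UNet, spec: UNetSpec):
        self.net = net
        self.spec = spec
        self.trained = False

    def predict_probabilities(self, frames: np.ndarray,
                              batch_size: int = 64) -> np.ndarray:
        """(N, H, W, 3) float frames -> (N, h, w) glottis probabilities at
        the model's input resolution."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        x = to_nchw(downsample_batch(frames, self.spec.input_size))
        logits = nn.predict_batched(self.net, x, batch_size)
        return 1.0 / (1.0 + np.exp(-logits[:, 0]))


def _pairs_to_arrays(pairs, spec: UNetSpec):
    frames = np.stack([f.pixels for f, _ in pairs])
    masks = np.stack([m.pixels.astype(np.float32) for _, m in pairs])
    x = to_nchw(downsample_batch(frames, spec.input_size))
    m = downsample_batch(masks[..., None], spec.input_size)[..., 0]
    y = (m >= 0.5).astype(np.float32)[:, None]  # (N,1,h,w)
    return x, y


def _append_degraded(x, y, cfg: TrainConfig, rng):
    """Abstention augmentation: degraded copies with empty target masks.

    Half the copies are blurred and hazed (motion blur through secretions),
    half get a bright secretion-like blob painted over the glottis. Both
    teach the network to abstain whenever the glottis is not sharply and
    entirely visible. Blur sigmas are stated at the nominal 128-px frame
    scale and rescaled to the model's input resolution.
    """
    from scipy.ndimage import gaussian_filter

    n_aug = int(round(cfg.degrade_fraction * len(x)))
    if n_aug == 0:
        return x, y
    idx = rng.choice(len(x), size=n_aug, replace=False)
    scale = x.shape[-1] / 128.0
    h, w = x.shape[2], x.shape[3]
    yy, xx = np.mgrid[0:h, 0:w]
    xa = np.empty_like(x[idx])
    for k, i in enumerate(idx):
        if rng.random() < 0.5:
            sigma = rng.uniform(*cfg.degrade_sigma_range) * scale
            blurred = gaussian_filter(x[i], (0, sigma, sigma))
            xa[k] = ((1 - cfg.haze_strength) * blurred
                     + cfg.haze_strength * cfg.haze_level)
        else:  # paint a blob over the mask's centre of mass
            m = y[i, 0]
            if m.sum() > 0:
                cy, cx = (np.argwhere(m > 0).mean(axis=0)
                          + rng.uniform(-3, 3, size=2) * scale)
            else:
                cy, cx = h / 2, w / 2
            r = np.sqrt(0.25 * h * w / np.pi) * rng.uniform(0.8, 1.2)
            d2 = ((xx - cx) / r) ** 2 + ((yy - cy) / r) ** 2
            alpha = 0.9 * np.clip((1.0 - d2) / 0.25, 0, 1).astype(np.float32)
            blob = np.array([0.95, 0.92, 0.85], dtype=np.float32)
            xa[k] = (x[i] * (1 - alpha)[None]
                     + blob[:, None, None] * alpha[None])
    ya = np.zeros_like(y[idx])
    return np.concatenate([x, xa]), np.concatenate([y, ya])


def train_unet(pairs, spec: UNetSpec | None = None,
               train_cfg: TrainConfig | None = None) -> SegmentationModel:
    """Train the weak-labelling U-Net on (frame, mask) pairs.

    Pairs are resized to the model input size; the loss is binary cross
    entropy plus soft Dice. Fully seeded.
    """
    if not pairs:
        raise ValueError("empty training set")
    if len(pairs) < 10:
        raise ValueError("need at least 10 segmentation pairs")
    spec = spec or UNetSpec()
    cfg = train_cfg or TrainConfig()
    x, y = _pairs_to_arrays(pairs, spec)
    rng = np.random.default_rng(cfg.seed)
    if cfg.degrade_fraction > 0:
        x, y = _append_degraded(x, y, cfg, rng)
    net = nn.UNet(in_channels=3, base_channels=spec.base_channels,
                  depth=spec.depth, rng=rng)
    nn.fit(net, x, y, nn.bce_dice, epochs=cfg.epochs,
           batch_size=cfg.batch_size, lr=cfg.learning_rate, seed=cfg.seed)
    model = SegmentationModel(net, spec)
    model.trained = True
    return model


def predict_mask(model: SegmentationModel, frame: FrameRecord | np.ndarray,
                 prob_threshold: float = 0.5) -> SegmentationMask:
    """Binary mask at the frame's original resolution."""
    pixels = frame.pixels if isinstance(frame, FrameRecord) else np.asarray(frame)
    probs = model.predict_probabilities(pixels[None])[0]
    small = (probs >= prob_threshold).astype(np.uint8)
    full = upsample_mask_nearest(small, pixels.shape[:2])
    return SegmentationMask(full)


def predict_masks(model: SegmentationModel, frames: np.ndarray,
                  prob_threshold: float = 0.5) -> list[SegmentationMask]:
    probs = model.predict_probabilities(frames)
    size = frames.shape[1:3]
    return [SegmentationMask(upsample_mask_nearest(
        (p >= prob_threshold).astype(np.uint8), size)) for p in probs]


def assign_quality_label(mask: SegmentationMask,
                         criteria: VisibilityCriteria | None = None) -> str:
    """good iff the mask is large enough and clear of the frame border."""
    criteria = criteria or VisibilityCriteria()
    px = mask.pixels
    h, w = px.shape
    if px.sum() < criteria.min_area_fraction * h * w:
        return POOR
    m = criteria.border_margin
    if m > 0:
        border = np.zeros_like(px, dtype=bool)
        border[:m, :] = border[-m:, :] = True
        border[:, :m] = border[:, -m:] = True
        if (px.astype(bool) & border).any():
            return POOR
    return GOOD


def weak_label_video(model: SegmentationModel, video: VideoRecord,
                     criteria: VisibilityCriteria | None = None) -> list[str]:
    """Weak good/poor label for every frame of one video."""
    criteria = criteria or VisibilityCriteria()
    frames = np.stack([f.pixels for f in video.frames])
    masks = predict_masks(model, frames, criteria.prob_threshold)
    return [assign_quality_label(m, criteria) for m in masks]


def weak_label_dataset(model: SegmentationModel, videos: list[VideoRecord],
                       criteria: VisibilityCriteria | None = None):
    """Label every frame of every video; returns a manifest-shaped table.

    Columns: patient_id, frame_index, referral_grade, quality_label. The
    ``quality_label`` column is the weak (model-derived) label, recorded as
    such so downstream evaluation can distinguish it from generator truth.
    """
    import pandas as pd

    rows = []
    for video in videos:
        labels = weak_label_video(model, video, criteria)
        for frame, lab in zip(video.frames, labels):
            rows.append((video.patient_id, frame.frame_index,
                         video.referral_grade, lab))
    return pd.DataFrame(rows, columns=["patient_id", "frame_index",
                                       "referral_grade", "quality_label"])


def held_out_dice(model: SegmentationModel, pairs) -> float:
    """Mean Dice of full-resolution predictions against exact masks."""
    scores = []
    for frame, mask in pairs:
        pred = predict_mask(model, frame)
        scores.append(dice(pred, mask))
    return float(np.mean(scores))
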