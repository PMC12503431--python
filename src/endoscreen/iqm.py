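"""Supervised frame-quality classification and frame selection (IQM stage 2b).

A small CNN classifier is trained on weak good/poor labels (produced by the
segmentation weak labeler) and scores every frame with a probability of
being good quality. Frames are then selected per patient: score at least
``threshold``, ranked by descending score (ties broken by ascending frame
index), optionally truncated to a frame budget ``max_n``. Videos whose
selection falls below a configurable minimum are flagged excluded, the way
studies drop patients with insufficient usable footage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .architectures import ArchSpec, build_classifier
from .core_data import FrameRecord, VideoRecord
from .imageops import downsample_batch, to_nchw
from .weaklabel import GOOD


class TrainingError(ValueError):
    pass


@dataclass
class ClassifierTrainConfig:
    epochs: int = 3
    learning_rate: float = 2e-3
    batch_size: int = 64
    seed: int = 0


def default_iqm_arch() -> ArchSpec:
    """Desk-scale quality classifier: reduced-width baseline CNN at 32x32."""
    return ArchSpec("baseline_cnn", input_size=(32, 32), width_multiplier=0.25)


class QualityModel:
    """Trained frame-quality classifier plus its input geometry."""

    def __init__(self, net: nn.Layer, spec: ArchSpec):
        self.net = net
        self.spec = spec
        self.trained = False

    def score(self, frames: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """(N, H, W, 3) float frames -> probability of 'good' per frame."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        x = to_nchw(downsample_batch(frames, self.spec.input_size))
        logits = nn.predict_batched(self.net, x, batch_size)
        return nn.softmax(logits)[:, 1]


def train_iqm(frames: np.ndarray, quality_labels, spec: ArchSpec | None = None,
              train_cfg: ClassifierTrainConfig | None = None) -> QualityModel:
    """Train the quality classifier on weakly labelled frames.

    ``quality_labels`` may be "good"/"poor" strings or a 0/1 array
    (1 = good). Both classes must be present.
    """
    spec = spec or default_iqm_arch()
    cfg = train_cfg or ClassifierTrainConfig()
    labels = np.asarray([
        1 if (lab == GOOD or lab == 1 or lab is True) else 0
        for lab in quality_labels], dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise TrainingError("quality training data contains a single class")
    x = to_nchw(downsample_batch(np.asarray(frames), spec.input_size))
    net = build_classifier(spec, seed=cfg.seed)
    nn.fit(net, x, labels, nn.softmax_cross_entropy, epochs=cfg.epochs,
           batch_size=cfg.batch_size, lr=cfg.learning_rate, seed=cfg.seed)
    model = QualityModel(net, spec)
    model.trained = True
    return model


def score_quality(model: QualityModel, frame: FrameRecord | np.ndarray) -> float:
    """Probability that one frame is good quality (deterministic)."""
    pixels = frame.pixels if isinstance(frame, FrameRecord) else np.asarray(frame)
    return float(model.score(pixels[None])[0])


@dataclass
class SelectionResult:
    indices: list[int]           # frame indices in descending-score order
    excluded: bool
    scores: np.ndarray = field(default=None, repr=False)

    def __len__(self):
        return len(self.indices)


def select_from_scores(scores: np.ndarray, frame_indices=None,
                       threshold: float = 0.5, max_n: int | None = None,
                       min_frames: int = 10) -> SelectionResult:
    """Core selection rule on precomputed quality scores."""
    scores = np.asarray(scores, dtype=float)
    if frame_indices is None:
        frame_indices = np.arange(len(scores))
    frame_indices = np.asarray(frame_indices)
    keep = scores >= threshold
    idx = frame_indices[keep]
    sc = scores[keep]
    order = np.lexsort((idx, -sc))  # score desc, frame index asc on ties
    ranked = idx[order]
    if max_n is not None:
        ranked = ranked[:max_n]
    return SelectionResult(indices=[int(i) for i in ranked],
                           excluded=len(ranked) < min_frames,
                           scores=scores)


def select_frames(video: VideoRecord, model: QualityModel,
                  threshold: float = 0.5, max_n: int | None = None,
                  min_frames: int = 10) -> SelectionResult:
    """Score a video's frames and select the good ones (top-n by score)."""
    frames = np.stack([f.pixels for f in video.frames])
    scores = model.score(frames)
    frame_indices = np.array([f.frame_index for f in video.frames])
    return select_from_scores(scores, frame_indices, threshold, max_n,
                              min_frames)
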