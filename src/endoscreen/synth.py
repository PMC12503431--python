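"""Synthetic nasopharyngoscopy-like cohorts with full ground truth.

Emulates the two data sources the pipeline needs without any download:

* segmentation pairs (sharp glottis-bearing frames + exact binary masks),
  standing in for an open glottis-segmentation benchmark, and
* per-patient frame sequences with a referral grade, where a controllable
  fraction of frames is degraded the way real endoscopy frames are: motion
  blur with secretion haze, bright secretion blobs occluding the target, or
  off-target content with no glottis at all.

The glottis is rendered as a dark, soft-edged, vertically elongated ellipse
on a low-frequency pink-tissue background. Referral-positive patients
(grades 2-3) additionally carry a lesion: a zero-mean luminance speckle
patch adjacent to the glottis, present in every glottis-bearing frame of
that patient. Because the speckle is a mid-frequency texture it survives
moderate downsampling but is destroyed by the blur of degraded frames, so
only good-quality frames carry usable disease signal — the property the
quality-filtering ablation probes.

Everything is deterministic in the master seed; per-patient streams are
derived via ``SeedSequence`` so cohorts are reproducible byte for byte.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core_data import (DatasetManifest, FrameRecord, SegmentationMask,
                        VideoRecord, save_frame, save_mask)

TISSUE_RGB = (0.78, 0.45, 0.40)
GLOTTIS_RGB = (0.10, 0.04, 0.05)
SECRETION_RGB = (0.95, 0.92, 0.85)
HAZE_LEVEL = 0.85      # grey level blended into blurred frames
HAZE_STRENGTH = 0.35   # blend weight of the haze in blurred frames
SENSOR_NOISE = 0.008
LESION_RADIUS_FRACTION = 0.14  # lesion patch radius / frame height
SPECKLE_SIGMA = 2.5            # px, correlation length of lesion speckle
GRADE3_BOOST = 1.5             # lesion-contrast multiplier for grade 3


@dataclass
class SceneParams:
    """Knobs of the synthetic scene generator (defaults are the study
    conditions used throughout the tests)."""

    image_size: tuple[int, int] = (128, 128)
    glottis_area_fraction: float = 0.05
    lesion_strength: float = 0.15
    blur_sigma_range: tuple[float, float] = (3.0, 6.0)
    occlusion_fraction: float = 0.3
    offtarget_probability: float = 0.25
    good_frame_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.glottis_area_fraction <= 0.3):
            raise ValueError("glottis_area_fraction must be in (0, 0.3]")
        if self.lesion_strength < 0:
            raise ValueError("lesion_strength must be >= 0")
        if not (0 <= self.occlusion_fraction <= 1):
            raise ValueError("occlusion_fraction must be in [0, 1]")
        if not (0 <= self.offtarget_probability <= 1):
            raise ValueError("offtarget_probability must be in [0, 1]")
        if not (0 < self.good_frame_fraction <= 1):
            raise ValueError("good_frame_fraction must be in (0, 1]")


@dataclass
class SyntheticCohort:
    """Videos plus per-frame generator truth (quality and masks)."""

    videos: list[VideoRecord]
    quality_truth: dict  # patient_id -> bool array, True = good frame
    masks: dict          # patient_id -> list[SegmentationMask]
    params: SceneParams = field(default=None)
    categories: dict = field(default_factory=dict)  # pid -> list[str]

    def video(self, patient_id) -> VideoRecord:
        for v in self.videos:
            if v.patient_id == str(patient_id):
                return v
        raise KeyError(patient_id)


def _rng_for(params: SceneParams, *tokens) -> np.random.Generator:
    entropy = [params.seed] + [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _smooth_noise(rng, h, w, sigma):
    field_ = gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
    std = field_.std()
    return field_ / std if std > 0 else field_


def _patient_style(prng, h, w):
    """Per-patient appearance: a persistent tissue field shared by every
    frame of one video plus an illumination tint — different endoscopes,
    lighting and anatomy make each patient's frames look alike and unlike
    other patients'."""
    base = np.empty((h, w, 3), dtype=np.float32)
    shared = _smooth_noise(prng, h, w, sigma=h / 8)
    for c, col in enumerate(TISSUE_RGB):
        own = _smooth_noise(prng, h, w, sigma=h / 10)
        base[:, :, c] = col + 0.06 * shared + 0.03 * own
    return {
        "base": base,
        "gain": prng.uniform(0.93, 1.07, size=3).astype(np.float32),
        "offset": np.float32(prng.uniform(-0.04, 0.04)),
    }


def _background(rng, h, w, style):
    img = style["base"] + 0.02 * _smooth_noise(rng, h, w, h / 10)[:, :, None]
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    img = img * (1.0 - 0.15 * r2)[:, :, None]
    return np.clip(img, 0, 1)


def _glottis(rng, params, h, w):
    """Render the dark glottal ellipse; returns (alpha map, exact mask,
    centre, semi-major axis extent)."""
    area = params.glottis_area_fraction * h * w * rng.uniform(0.75, 1.25)
    aspect = rng.uniform(2.2, 3.2)          # vertical elongation
    b = np.sqrt(area / (np.pi * aspect))    # semi-minor (horizontal)
    a = aspect * b                          # semi-major (vertical)
    theta = np.deg2rad(rng.uniform(-25, 25))
    ext_x = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    ext_y = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    margin = 6.0
    cx = rng.uniform(margin + ext_x, w - margin - ext_x)
    cy = rng.uniform(margin + ext_y, h - margin - ext_y)
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / b
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / a
    d = u ** 2 + v ** 2
    alpha = np.clip((1.0 - d) / 0.15, 0, 1).astype(np.float32)
    mask = (d <= 1.0).astype(np.uint8)
    return alpha, mask, (cx, cy), max(ext_x, ext_y)


def _paint_lesion(rng, img, centre, extent, strength):
    h, w = img.shape[:2]
    r = LESION_RADIUS_FRACTION * h
    angle = rng.uniform(0, 2 * np.pi)
    dist = extent + 0.6 * r
    cx = np.clip(centre[0] + dist * np.cos(angle), r + 2, w - r - 2)
    cy = np.clip(centre[1] + dist * np.sin(angle), r + 2, h - r - 2)
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = ((xx - cx) / r) ** 2 + ((yy - cy) / r) ** 2
    window = np.clip((1.0 - d2) / 0.3, 0, 1)
    speckle = _smooth_noise(rng, h, w, SPECKLE_SIGMA)
    img += (strength * window * speckle)[:, :, None]
    return img


def _occlude(rng, img, centre, fraction):
    h, w = img.shape[:2]
    r = np.sqrt(max(fraction, 1e-3) * h * w / np.pi)
    cx = np.clip(centre[0] + rng.uniform(-10, 10), 0, w - 1)
    cy = np.clip(centre[1] + rng.uniform(-10, 10), 0, h - 1)
    yy, xx = np.mgrid[0:h, 0:w]
    wobble = 1.0 + 0.25 * _smooth_noise(rng, h, w, h / 10)
    d2 = (((xx - cx) / r) ** 2 + ((yy - cy) / r) ** 2) / np.maximum(wobble, 0.3)
    alpha = 0.85 * np.clip((1.0 - d2) / 0.25, 0, 1)
    blob = np.array(SECRETION_RGB, dtype=np.float32)
    return img * (1 - alpha[:, :, None]) + blob[None, None, :] * alpha[:, :, None]


def _render_scene(rng, params, referral_grade, style=None, with_glottis=True):
    """Sharp scene + exact mask (empty when off-target)."""
    h, w = params.image_size
    if style is None:
        style = _patient_style(rng, h, w)
    img = _background(rng, h, w, style)
    if not with_glottis:
        smudge = _smooth_noise(rng, h, w, h / 6)
        img = np.clip(img + 0.10 * smudge[:, :, None], 0, 1)
        return img, np.zeros((h, w), dtype=np.uint8), (w / 2, h / 2), 0.0
    alpha, mask, centre, extent = _glottis(rng, params, h, w)
    glottis = np.array(GLOTTIS_RGB, dtype=np.float32)
    img = img * (1 - alpha[:, :, None]) + glottis[None, None, :] * alpha[:, :, None]
    if referral_grade >= 2 and params.lesion_strength > 0:
        strength = params.lesion_strength * (GRADE3_BOOST if referral_grade == 3 else 1.0)
        img = _paint_lesion(rng, img, centre, extent, strength)
    return np.clip(img, 0, 1), mask, centre, extent


def _finish(rng, img, style=None):
    if style is not None:  # patient-wide illumination tint
        img = img * style["gain"][None, None, :] + style["offset"]
    img = img + SENSOR_NOISE * rng.standard_normal(img.shape)
    return np.clip(img, 0, 1).astype(np.float32)


def generate_video(params: SceneParams, patient_id, n_frames: int,
                   referral_grade: int):
    """Generate one patient's frame sequence.

    Returns ``(VideoRecord, quality_truth, masks)`` where ``quality_truth``
    is a boolean array (True = good frame) with exactly
    ``round(good_frame_fraction * n_frames)`` good frames, and ``masks``
    holds the exact glottis mask of each frame (empty for off-target
    frames). Frame 0 is always a good frame — it serves as the index frame
    of relevance for similarity filtering downstream.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _rng_for(params, "video", patient_id)
    h, w = params.image_size
    style = _patient_style(_rng_for(params, "style", patient_id), h, w)
    n_good = int(round(params.good_frame_fraction * n_frames))
    n_good = max(n_good, 1)
    good_idx = set(rng.choice(n_frames, size=n_good, replace=False).tolist())
    if 0 not in good_idx:  # keep the count, swap one slot for frame 0
        good_idx.discard(max(good_idx))
        good_idx.add(0)
    frames, truth, masks = [], np.zeros(n_frames, dtype=bool), []
    categories = []
    for i in range(n_frames):
        frng = _rng_for(params, "frame", patient_id, i)
        if i in good_idx:
            img, mask, _, _ = _render_scene(frng, params, referral_grade, style)
            img = gaussian_filter(img, (0.6, 0.6, 0))  # mild optical softness
            truth[i] = True
            categories.append("good")
        else:
            if frng.random() < params.offtarget_probability:
                img, mask, _, _ = _render_scene(frng, params, referral_grade,
                                                style, with_glottis=False)
                categories.append("offtarget")
            elif frng.random() < 0.5:
                img, mask, _, _ = _render_scene(frng, params, referral_grade,
                                                style)
                sigma = frng.uniform(*params.blur_sigma_range)
                img = gaussian_filter(img, (sigma, sigma, 0))
                img = (1 - HAZE_STRENGTH) * img + HAZE_STRENGTH * HAZE_LEVEL
                categories.append("blur")
            else:
                img, mask, centre, _ = _render_scene(frng, params,
                                                     referral_grade, style)
                img = _occlude(frng, img, centre, params.occlusion_fraction)
                categories.append("occlusion")
        img = _finish(frng, img, style)
        frames.append(FrameRecord(str(patient_id), i, img))
        masks.append(SegmentationMask(mask, str(patient_id), i))
    return VideoRecord(str(patient_id), frames, referral_grade), truth, masks, categories


def generate_cohort(params: SceneParams, n_patients: int,
                    positive_fraction: float = 0.7,
                    frames_per_patient: int = 100) -> SyntheticCohort:
    """Generate a cohort; ``round(positive_fraction * n_patients)`` patients
    get grade 2 or 3 (split evenly, remainder to grade 2), the rest grade 1."""
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if not (0 < positive_fraction < 1):
        raise ValueError("positive_fraction must be in (0, 1)")
    n_pos = int(round(positive_fraction * n_patients))
    n_grade2 = (n_pos + 1) // 2
    grades = [2] * n_grade2 + [3] * (n_pos - n_grade2) + [1] * (n_patients - n_pos)
    rng = _rng_for(params, "cohort")
    rng.shuffle(grades)
    videos, truth, masks, cats = [], {}, {}, {}
    for i, grade in enumerate(grades):
        pid = f"p{i:03d}"
        video, q, m, c = generate_video(params, pid, frames_per_patient, grade)
        videos.append(video)
        truth[pid] = q
        masks[pid] = m
        cats[pid] = c
    return SyntheticCohort(videos, truth, masks, params, cats)


def generate_segmentation_set(params: SceneParams, n: int):
    """n sharp glottis-bearing frames with exact masks (benchmark stand-in).

    About 40% of the frames carry a lesion, mirroring the healthy/unhealthy
    mix of public glottis-segmentation corpora; lesions do not alter masks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = []
    for i in range(n):
        rng = _rng_for(params, "segset", i)
        grade = 2 if rng.random() < 0.4 else 1
        style = _patient_style(rng, *params.image_size)
        img, mask, _, _ = _render_scene(rng, params, grade, style)
        img = gaussian_filter(img, (0.6, 0.6, 0))
        img = _finish(rng, img, style)
        pairs.append((FrameRecord(f"seg{i:04d}", i, img), SegmentationMask(mask)))
    return pairs


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> str:
    """Write frames, masks, quality truth and a manifest CSV; returns the
    manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows, truth_rows = [], []
    for video in cohort.videos:
        pdir = os.path.join(out_dir, video.patient_id)
        os.makedirs(pdir, exist_ok=True)
        q = cohort.quality_truth[video.patient_id]
        for frame, mask in zip(video.frames, cohort.masks[video.patient_id]):
            rel = os.path.join(video.patient_id, f"f{frame.frame_index:04d}.png")
            save_frame(os.path.join(out_dir, rel), frame.pixels)
            if mask.area:
                save_mask(os.path.join(pdir, f"f{frame.frame_index:04d}_seg.png"), mask)
            rows.append((video.patient_id, rel, frame.frame_index,
                         video.referral_grade))
            truth_rows.append((video.patient_id, frame.frame_index,
                               int(q[frame.frame_index])))
    manifest = pd.DataFrame(rows, columns=["patient_id", "frame_path",
                                           "frame_index", "referral_grade"])
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows, columns=["patient_id", "frame_index", "good"]) \
        .to_csv(os.path.join(out_dir, "quality_truth.csv"), index=False)
    return manifest_path


def write_segmentation_set(pairs, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for frame, mask in pairs:
        save_frame(os.path.join(out_dir, f"{frame.patient_id}.png"), frame.pixels)
        save_mask(os.path.join(out_dir, f"{frame.patient_id}_seg.png"), mask)


def frames_array(video: VideoRecord) -> np.ndarray:
    """Stack a video's frames into (T, H, W, 3) float32."""
    return np.stack([f.pixels for f in video.frames])
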