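"""Domain types and I/O for nasopharyngoscopy frame datasets.

Videos are represented as ordered sequences of still frames on disk plus a
CSV manifest (one row per frame). All images are converted to RGB float in
[0, 1] at load time; grayscale inputs are channel-replicated. Segmentation
pairs follow the ``<name>.png`` + ``<name>_seg.png`` convention common to
glottis-segmentation benchmarks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["patient_id", "frame_path", "frame_index", "referral_grade"]
VALID_GRADES = (1, 2, 3)
MASK_SUFFIX = "_seg"


class ManifestError(ValueError):
    """Schema or invariant violation in a dataset manifest."""


@dataclass
class FrameRecord:
    """One video frame: RGB pixels in [0,1] with patient linkage."""

    patient_id: str
    frame_index: int
    pixels: np.ndarray  # (H, W, 3) float32 in [0, 1]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be HxWx3")
        h, w = self.pixels.shape[:2]
        if h < 32 or w < 32:
            raise ValueError("frames must be at least 32x32")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class VideoRecord:
    """Ordered frames of one patient plus the referral grade.

    ``binary_label`` encodes the triage decision: 0 for grade 1 (no
    referral), 1 for grades 2-3 (referral).
    """

    patient_id: str
    frames: list[FrameRecord]
    referral_grade: int

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a video needs at least one frame")
        if self.referral_grade not in VALID_GRADES:
            raise ValueError(f"referral_grade must be in {VALID_GRADES}")
        idx = [f.frame_index for f in self.frames]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate frame_index within a patient")
        self.frames = sorted(self.frames, key=lambda f: f.frame_index)

    @property
    def binary_label(self) -> int:
        return 0 if self.referral_grade == 1 else 1

    def __len__(self):
        return len(self.frames)


@dataclass
class SegmentationMask:
    """Binary glottis mask aligned with one frame."""

    pixels: np.ndarray  # (H, W) in {0, 1}
    patient_id: str | None = None
    frame_index: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_fraction(self) -> float:
        return self.area / self.pixels.size


@dataclass
class DatasetManifest:
    """Frame-level manifest; thin wrapper over a validated DataFrame."""

    frame: pd.DataFrame
    root: str = "."

    def __post_init__(self):
        _validate_manifest_frame(self.frame)

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["patient_id"]))

    def rows_for(self, patient_id) -> pd.DataFrame:
        return self.frame[self.frame["patient_id"].astype(str) == str(patient_id)]

    def __len__(self):
        return len(self.frame)


def _validate_manifest_frame(df: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest is missing columns: {missing}")
    for i, g in enumerate(df["referral_grade"]):
        if int(g) not in VALID_GRADES:
            raise ManifestError(f"row {i}: referral_grade {g} not in {VALID_GRADES}")
    dup = df.duplicated(subset=["patient_id", "frame_index"])
    if dup.any():
        raise ManifestError(
            f"duplicate (patient_id, frame_index) at rows {list(df.index[dup])}")


def read_manifest(path: str | os.PathLike, check_files: bool = True) -> DatasetManifest:
    """Read and validate a CSV manifest; frame paths are relative to it."""
    df = pd.read_csv(path)
    _validate_manifest_frame(df)
    root = os.path.dirname(os.fspath(path)) or "."
    if check_files:
        for p in df["frame_path"]:
            full = os.path.join(root, p)
            if not os.path.exists(full):
                raise FileNotFoundError(f"manifest references missing file: {full}")
    df = df.copy()
    df["frame_index"] = df["frame_index"].astype(int)
    df["referral_grade"] = df["referral_grade"].astype(int)
    return DatasetManifest(df, root=root)


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    manifest.frame.to_csv(path, index=False)


def decode_image(path: str | os.PathLike) -> np.ndarray:
    """Decode PNG/JPEG to HxWx3 float32 in [0,1] (8- or 16-bit sources)."""
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        img = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(np.float32) / 65535.0
    else:
        img = np.clip(arr.astype(np.float32), 0, 1)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img


def load_video(manifest: DatasetManifest, patient_id) -> VideoRecord:
    """Decode one patient's frames, sorted by frame_index."""
    rows = manifest.rows_for(patient_id)
    if rows.empty:
        raise KeyError(f"patient {patient_id!r} not in manifest")
    grades = rows["referral_grade"].unique()
    if len(grades) != 1:
        raise ManifestError(f"patient {patient_id!r} has conflicting grades {grades}")
    frames = [
        FrameRecord(str(patient_id), int(r.frame_index),
                    decode_image(os.path.join(manifest.root, r.frame_path)))
        for r in rows.itertuples()
    ]
    return VideoRecord(str(patient_id), frames, int(grades[0]))


def load_mask_pairs(directory: str | os.PathLike,
                    mask_suffix: str = MASK_SUFFIX):
    """Load (frame, mask) pairs from paired PNGs in one directory.

    Every ``<name>.png`` must have a ``<name><mask_suffix>.png`` partner;
    grayscale masks are binarised at 0.5 of full range.
    """
    directory = os.fspath(directory)
    names = sorted(os.listdir(directory))
    images = [n for n in names
              if n.lower().endswith((".png", ".jpg", ".jpeg"))
              and mask_suffix not in os.path.splitext(n)[0]]
    pairs = []
    for name in images:
        stem, ext = os.path.splitext(name)
        mask_name = f"{stem}{mask_suffix}.png"
        mask_path = os.path.join(directory, mask_name)
        if not os.path.exists(mask_path):
            raise FileNotFoundError(f"no mask {mask_name} for image {name}")
        img = decode_image(os.path.join(directory, name))
        raw = iio.imread(mask_path)
        if raw.ndim == 3:
            raw = raw[..., 0]
        mask = (raw.astype(np.float32) / max(float(raw.max()), 1.0)) >= 0.5
        if mask.shape != img.shape[:2]:
            raise ValueError(
                f"{name}: mask shape {mask.shape} != image shape {img.shape[:2]}")
        frame = FrameRecord(stem, len(pairs), img)
        pairs.append((frame, SegmentationMask(mask.astype(np.uint8))))
    return pairs


def save_frame(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write a float [0,1] RGB frame as 8-bit PNG."""
    arr = np.clip(np.asarray(pixels) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def save_mask(path: str | os.PathLike, mask: SegmentationMask) -> None:
    iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))
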