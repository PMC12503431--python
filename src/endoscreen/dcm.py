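"""Disease classification module: frame classifier + patient aggregation.

Frames inherit their patient's binary referral label (grade 1 = 0, grades
2-3 = 1) for training. At inference every selected frame receives a
referral probability and the patient-level probability is their arithmetic
mean ("bagging" over the frames of one video); the referral decision
thresholds that mean. Splits are always at the patient level — a leakage
guard refuses training data whose patients overlap the declared test set.

``run_experiment`` is the frame-budget ablation harness: it trains and
evaluates the full pipeline without quality filtering and with filtering at
several per-patient frame budgets, reporting patient-level accuracy,
weighted F1, AUROC and AUPRC per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as _nd_rotate

from . import nn
from .architectures import ArchSpec, build_classifier
from .core_data import VideoRecord
from .imageops import downsample_batch, to_nchw
from .iqm import (ClassifierTrainConfig, QualityModel, TrainingError,
                  default_iqm_arch, select_from_scores, train_iqm)
from .metrics import MetricsReport, compute_report, patient_split
from .synth import SceneParams, SyntheticCohort, frames_array, generate_segmentation_set
from .weaklabel import (GOOD, SegmentationModel, TrainConfig, UNetSpec,
                        VisibilityCriteria, assign_quality_label, train_unet)


class LeakageError(ValueError):
    """Raised when train and test sets share a patient."""


@dataclass
class FocalLossParams:
    gamma: float = 2.0
    alpha: float = 0.25
    enabled: bool = True

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


def focal_loss(p, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """-alpha * (1-p)^gamma * log(p), averaged over a batch.

    ``p`` is the predicted probability of the true class, clipped at 1e-7;
    gamma = 0, alpha = 1 recovers plain cross entropy.
    """
    p = np.clip(np.asarray(p, dtype=float), 1e-7, 1.0)
    return float(np.mean(-alpha * (1.0 - p) ** gamma * np.log(p)))


@dataclass
class PatientPrediction:
    patient_id: str
    frame_probabilities: list[float]
    aggregate_probability: float | None
    predicted_label: int | None
    excluded: bool = False


class DiseaseModel:
    """Trained frame-level referral classifier."""

    def __init__(self, net: nn.Layer, spec: ArchSpec):
        self.net = net
        self.spec = spec
        self.trained = False

    def frame_probabilities(self, frames: np.ndarray,
                            batch_size: int = 128) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model has not been trained")
        x = to_nchw(downsample_batch(frames, self.spec.input_size))
        logits = nn.predict_batched(self.net, x, batch_size)
        return nn.softmax(logits)[:, 1]


def default_dcm_arch() -> ArchSpec:
    """Desk-scale referral classifier: reduced-width baseline CNN at 64x64
    (enough resolution to resolve the lesion texture)."""
    return ArchSpec("baseline_cnn", input_size=(64, 64), width_multiplier=0.25)


def _augment(x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Horizontal flip + brightness jitter + small rotation, doubling the set."""
    aug = x[:, :, :, ::-1].copy()
    shift = rng.uniform(-0.08, 0.08, size=(len(aug), 1, 1, 1)).astype(np.float32)
    aug = np.clip(aug + shift, 0, 1)
    angles = rng.uniform(-10, 10, size=len(aug))
    for i in range(len(aug)):
        aug[i] = _nd_rotate(aug[i], angles[i], axes=(1, 2), reshape=False,
                            order=1, mode="nearest")
    return np.concatenate([x, aug]), np.concatenate([y, y])


def train_dcm(frames: np.ndarray, binary_labels, patient_ids=None,
              spec: ArchSpec | None = None,
              loss: FocalLossParams | None = None,
              augment: bool = False,
              train_cfg: ClassifierTrainConfig | None = None,
              test_patient_ids=None) -> DiseaseModel:
    """Train the frame-level referral classifier.

    ``frames`` is (N, H, W, 3); ``binary_labels`` per frame (frames inherit
    their patient's label). If ``patient_ids`` and ``test_patient_ids`` are
    given, any overlap raises ``LeakageError`` before training starts.
    """
    spec = spec or default_dcm_arch()
    loss = loss or FocalLossParams()
    cfg = train_cfg or ClassifierTrainConfig()
    y = np.asarray(binary_labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise TrainingError("both referral classes are required for training")
    if patient_ids is not None and test_patient_ids is not None:
        overlap = set(map(str, patient_ids)) & set(map(str, test_patient_ids))
        if overlap:
            raise LeakageError(f"patients in both train and test: {sorted(overlap)}")
    x = to_nchw(downsample_batch(np.asarray(frames), spec.input_size))
    rng = np.random.default_rng(cfg.seed)
    if augment:
        x, y = _augment(x, y, rng)
    if loss.enabled:
        def loss_fn(logits, labels):
            return nn.focal_cross_entropy(logits, labels, gamma=loss.gamma,
                                          alpha=loss.alpha)
    else:
        # prevalence-corrected cross entropy keeps the decision threshold
        # meaningful under the cohort's referral-class imbalance
        counts = np.bincount(y, minlength=2).astype(np.float64)
        weights = y.size / (2.0 * np.maximum(counts, 1))

        def loss_fn(logits, labels):
            return nn.softmax_cross_entropy(logits, labels, weights)
    net = build_classifier(spec, seed=cfg.seed)
    nn.fit(net, x, y, loss_fn, epochs=cfg.epochs, batch_size=cfg.batch_size,
           lr=cfg.learning_rate, seed=cfg.seed)
    model = DiseaseModel(net, spec)
    model.trained = True
    return model


def aggregate_probabilities(frame_probs) -> float:
    """Patient-level probability: the arithmetic mean of frame probabilities."""
    return float(np.mean(frame_probs))


def predict_patient(model: DiseaseModel, video: VideoRecord,
                    selection=None, threshold: float = 0.5) -> PatientPrediction:
    """Referral prediction for one patient from (selected) frame probabilities."""
    if selection is None:
        chosen = video.frames
    else:
        wanted = set(int(i) for i in selection)
        chosen = [f for f in video.frames if f.frame_index in wanted]
    if not chosen:
        return PatientPrediction(video.patient_id, [], None, None, excluded=True)
    frames = np.stack([f.pixels for f in chosen])
    probs = model.frame_probabilities(frames)
    agg = aggregate_probabilities(probs)
    return PatientPrediction(video.patient_id, [float(p) for p in probs],
                             agg, int(agg >= threshold))


# ---------------------------------------------------------------------------
# Frame-budget ablation harness
# ---------------------------------------------------------------------------

DEFAULT_CONDITIONS = ("none", 10, 30, 50, "unlimited")


@dataclass
class AblationConfig:
    """Study conditions and desk-scale training budgets for the ablation."""

    conditions: tuple = DEFAULT_CONDITIONS
    dcm_arch: ArchSpec = field(default_factory=default_dcm_arch)
    iqm_arch: ArchSpec = field(default_factory=default_iqm_arch)
    unet_spec: UNetSpec = field(default_factory=UNetSpec)
    n_segmentation_pairs: int = 500
    criteria: VisibilityCriteria = field(default_factory=VisibilityCriteria)
    focal: FocalLossParams = field(
        default_factory=lambda: FocalLossParams(enabled=False))
    dcm_epochs: int = 6         # cap; actual epochs follow the pass budget
    dcm_pass_budget: int = 1800  # frame-passes per DCM training (equal per
                                 # condition, so conditions differ by data
                                 # quality, not optimisation budget)
    iqm_epochs: int = 2
    iqm_frames_cap: int = 40     # per-patient frames for IQM training
    unet_epochs: int = 5
    learning_rate: float = 2e-3
    batch_size: int = 32
    augment: bool = False
    quality_threshold: float = 0.5
    calibrate_decision_threshold: bool = True
    min_frames: int = 10
    test_fraction: float = 0.2
    train_frames_cap: int = 50  # per-patient training-frame budget (desk scale)


def _weak_labels_for(seg_model: SegmentationModel, frames: np.ndarray,
                     criteria: VisibilityCriteria) -> np.ndarray:
    """Vector of weak labels (1 = good) for one patient's frame stack."""
    probs = seg_model.predict_probabilities(frames)
    out = np.zeros(len(frames), dtype=np.int64)
    for i, p in enumerate(probs):
        mask = (p >= criteria.prob_threshold).astype(np.uint8)
        from .core_data import SegmentationMask
        out[i] = int(assign_quality_label(SegmentationMask(mask), criteria) == GOOD)
    return out


def train_weak_labeler(params: SceneParams, cfg: AblationConfig,
                       seed: int = 0) -> SegmentationModel:
    """Segmentation model trained on a synthetic benchmark-style pair set."""
    pairs = generate_segmentation_set(params, cfg.n_segmentation_pairs)
    return train_unet(pairs, cfg.unet_spec,
                      TrainConfig(epochs=cfg.unet_epochs, seed=seed))


def run_experiment(cohort: SyntheticCohort, seeds=(0, 1, 2, 3, 4),
                   config: AblationConfig | None = None,
                   weak_labeler: SegmentationModel | None = None,
                   hog_retained: dict | None = None) -> pd.DataFrame:
    """Train and evaluate the DCM under each quality-filtering condition.

    Conditions: "none" (no quality filtering; all frames train and test) and
    per-patient frame budgets n = 10, 30, 50 and "unlimited" (every frame
    the quality classifier accepts). Each seed redraws the patient-level
    train/test split and all weight initialisations. Returns a tidy frame
    with one row per (seed, condition) plus seed-mean rows (seed = "mean").
    """
    config = config or AblationConfig()
    if len(cohort.videos) < 20:
        raise ValueError("ablation needs a cohort of at least 20 patients")
    labels = {v.patient_id: v.binary_label for v in cohort.videos}
    if weak_labeler is None:
        weak_labeler = train_weak_labeler(cohort.params or SceneParams(), config)

    # Per-patient frame stacks, downsampled once for each consumer.
    stacks = {v.patient_id: frames_array(v) for v in cohort.videos}
    dcm_in = {pid: downsample_batch(s, config.dcm_arch.input_size)
              for pid, s in stacks.items()}
    iqm_in = {pid: downsample_batch(s, config.iqm_arch.input_size)
              for pid, s in stacks.items()}
    seg_in = {pid: downsample_batch(s, weak_labeler.spec.input_size)
              for pid, s in stacks.items()}
    del stacks
    weak = {pid: _weak_labels_for(weak_labeler, s, config.criteria)
            for pid, s in seg_in.items()}
    del seg_in

    if hog_retained is None:
        keep = {pid: np.ones(len(weak[pid]), dtype=bool) for pid in labels}
    else:
        keep = {pid: np.asarray(hog_retained[pid], dtype=bool) for pid in labels}

    rows = []
    for seed in seeds:
        train_ids, test_ids = patient_split(labels, config.test_fraction,
                                            stratify=True, seed=seed)
        irng = np.random.default_rng((seed, 17))
        iqm_pick = {}
        for p in train_ids:
            avail = np.flatnonzero(keep[p])
            if len(avail) > config.iqm_frames_cap:
                avail = np.sort(irng.choice(avail, config.iqm_frames_cap,
                                            replace=False))
            iqm_pick[p] = avail
        iqm_x = np.concatenate([iqm_in[p][iqm_pick[p]] for p in train_ids])
        iqm_y = np.concatenate([weak[p][iqm_pick[p]] for p in train_ids])
        iqm_model = train_iqm(
            iqm_x, iqm_y, config.iqm_arch,
            ClassifierTrainConfig(epochs=config.iqm_epochs,
                                  learning_rate=config.learning_rate,
                                  batch_size=config.batch_size, seed=seed))
        # frames dropped by the HOG similarity stage never reach the
        # quality classifier's selection pool
        scores = {pid: np.where(keep[pid], iqm_model.score(iqm_in[pid]), -1.0)
                  for pid in labels}

        for condition in config.conditions:
            sel = _condition_selection(condition, labels, scores, config, seed)
            included_train = [p for p in train_ids if sel[p] is not None]
            included_test = [p for p in test_ids if sel[p] is not None]
            if (len({labels[p] for p in included_train}) < 2
                    or len({labels[p] for p in included_test}) < 2):
                raise TrainingError(
                    f"condition {condition!r}: exclusions removed a class")
            x_tr = np.concatenate([dcm_in[p][sel[p]["train"]]
                                   for p in included_train])
            y_tr = np.concatenate([np.full(len(sel[p]["train"]), labels[p])
                                   for p in included_train])
            pid_tr = np.concatenate([np.full(len(sel[p]["train"]), p)
                                     for p in included_train])
            epochs = int(np.clip(round(config.dcm_pass_budget / len(x_tr)),
                                 2, config.dcm_epochs))
            dcm_model = train_dcm(
                x_tr, y_tr, pid_tr, config.dcm_arch, config.focal,
                augment=config.augment,
                train_cfg=ClassifierTrainConfig(
                    epochs=epochs,
                    learning_rate=config.learning_rate,
                    batch_size=config.batch_size, seed=seed),
                test_patient_ids=included_test)
            threshold = 0.5
            if config.calibrate_decision_threshold:
                tr_agg = np.array([aggregate_probabilities(
                    dcm_model.frame_probabilities(
                        dcm_in[p][sel[p]["eval"][:30]]))
                    for p in included_train])
                tr_lab = np.array([labels[p] for p in included_train])
                threshold = _calibrate_threshold(tr_agg, tr_lab)
            y_true, agg = [], []
            for p in included_test:
                probs = dcm_model.frame_probabilities(dcm_in[p][sel[p]["eval"]])
                y_true.append(labels[p])
                agg.append(aggregate_probabilities(probs))
            report = compute_report(y_true, agg, threshold, level="patient")
            rows.append({"seed": seed, "condition": str(condition),
                         "n_excluded": sum(1 for p in labels if sel[p] is None),
                         **report.as_dict()})

    df = pd.DataFrame(rows)
    means = (df.groupby("condition", sort=False)
             [["accuracy", "weighted_f1", "auroc", "auprc"]].mean()
             .reset_index())
    means.insert(0, "seed", "mean")
    return pd.concat([df, means], ignore_index=True)


def _calibrate_threshold(train_aggregates, train_labels) -> float:
    """Decision threshold maximising balanced accuracy on the training
    patients' aggregated probabilities (referral studies rarely publish
    their operating point; calibrating on training data is the standard
    leak-free choice). Candidates are midpoints between adjacent sorted
    aggregates; ties prefer the candidate closest to 0.5."""
    from .metrics import balanced_accuracy

    order = np.sort(np.unique(train_aggregates))
    if len(order) < 2:
        return 0.5
    candidates = np.concatenate([[0.5], (order[1:] + order[:-1]) / 2.0])
    best, best_score = 0.5, -1.0
    for c in candidates:
        score = balanced_accuracy(train_labels,
                                  (train_aggregates >= c).astype(int))
        if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12
                and abs(c - 0.5) < abs(best - 0.5)):
            best, best_score = float(c), score
    return best


def _condition_selection(condition, labels, scores, config: AblationConfig,
                         seed: int):
    """Per-patient train/eval frame positions for one ablation condition.

    Returns pid -> {"train": positions, "eval": positions} or None when the
    patient is excluded (insufficient good frames). Training positions are
    additionally capped at ``train_frames_cap`` per patient (highest-scoring
    first; a seeded random subset under "none", which has no scores).
    """
    cap = config.train_frames_cap
    out = {}
    for pid in labels:
        n_frames = len(scores[pid])
        if condition == "none":
            import zlib
            rng = np.random.default_rng((seed, zlib.crc32(str(pid).encode())))
            train_pos = (np.sort(rng.choice(n_frames, size=min(cap, n_frames),
                                            replace=False))
                         if n_frames > cap else np.arange(n_frames))
            out[pid] = {"train": train_pos, "eval": np.arange(n_frames)}
            continue
        max_n = None if condition == "unlimited" else int(condition)
        res = select_from_scores(scores[pid], threshold=config.quality_threshold,
                                 max_n=max_n, min_frames=config.min_frames)
        if res.excluded:
            out[pid] = None
            continue
        pos = np.array(res.indices)  # descending score order
        out[pid] = {"train": pos[:cap], "eval": pos}
    return out
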