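"""Self-contained evaluation statistics and leak-free patient splitting.

Accuracy, weighted F1, AUROC (Mann-Whitney formulation, ties counted 1/2)
and AUPRC (average precision with step interpolation and tied-score
grouping) are implemented directly so their definitions are explicit and
testable against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given labels (e.g. AUROC
    with a single class); never silently mapped to 0 or 1."""


@dataclass
class MetricsReport:
    accuracy: float
    weighted_f1: float
    auroc: float
    auprc: float
    n_samples: int
    level: str = "patient"  # or "frame"

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "weighted_f1": self.weighted_f1,
            "auroc": self.auroc, "auprc": self.auprc,
            "n_samples": self.n_samples, "level": self.level,
        }


def _check_lengths(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError(f"length mismatch or empty input: {a.shape} vs {b.shape}")
    return a, b


def accuracy(labels, predictions) -> float:
    labels, predictions = _check_lengths(labels, predictions)
    return float((labels == predictions).mean())


def weighted_f1(labels, predictions) -> float:
    """Per-class F1 averaged with weights equal to true-class support
    fractions; a class with precision + recall = 0 contributes F1 = 0."""
    labels, predictions = _check_lengths(labels, predictions)
    total = 0.0
    for cls in np.unique(labels):
        support = (labels == cls).sum()
        tp = ((labels == cls) & (predictions == cls)).sum()
        pred_pos = (predictions == cls).sum()
        if tp == 0:
            f1 = 0.0
        else:
            precision = tp / pred_pos
            recall = tp / support
            f1 = 2 * precision * recall / (precision + recall)
        total += (support / labels.size) * f1
    return float(total)


def auroc(labels, scores) -> float:
    """P(score of random positive > score of random negative), ties 1/2."""
    labels, scores = _check_lengths(labels, scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels, scores) -> float:
    """Average precision: sum of (recall increment x precision) over
    descending score thresholds, grouping tied scores."""
    labels, scores = _check_lengths(labels, scores)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:  # tied group enters together
            j += 1
        tp += int((labels[i:j] == 1).sum())
        fp += int((labels[i:j] == 0).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


def balanced_accuracy(labels, predictions) -> float:
    labels, predictions = _check_lengths(labels, predictions)
    recalls = []
    for cls in np.unique(labels):
        sel = labels == cls
        recalls.append((predictions[sel] == cls).mean())
    return float(np.mean(recalls))


def dice(mask_a, mask_b) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(getattr(mask_a, "pixels", mask_a)).astype(bool)
    b = np.asarray(getattr(mask_b, "pixels", mask_b)).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def compute_report(labels, scores, threshold: float = 0.5,
                   level: str = "patient") -> MetricsReport:
    """All four metrics from scores; hard labels via ``score >= threshold``."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    preds = (scores >= threshold).astype(int)
    return MetricsReport(
        accuracy=accuracy(labels, preds),
        weighted_f1=weighted_f1(labels, preds),
        auroc=auroc(labels, scores),
        auprc=auprc(labels, scores),
        n_samples=len(labels),
        level=level,
    )


def patient_split(patient_labels: dict, test_fraction: float = 0.2,
                  stratify: bool = True, seed: int = 0):
    """Split patient ids into disjoint, exhaustive (train, test) sets.

    ``patient_labels`` maps patient id -> binary label. Test size is
    round(test_fraction * n); under stratification every class keeps at
    least one test patient and per-class counts follow the same rounding.
    """
    ids = np.array(list(patient_labels.keys()), dtype=object)
    labels = np.array([patient_labels[i] for i in ids])
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_test = int(round(test_fraction * n))
    rng = np.random.default_rng(seed)
    if not stratify:
        perm = rng.permutation(n)
        test_idx = set(perm[:n_test].tolist())
    else:
        classes = np.unique(labels)
        if any((labels == c).sum() < 2 for c in classes):
            raise ValueError("stratified split needs >= 2 patients per class")
        per_class = {}
        for c in classes:
            n_c = int((labels == c).sum())
            per_class[c] = max(1, int(round(test_fraction * n_c)))
        # reconcile the per-class sum with the overall rounding target
        diff = n_test - sum(per_class.values())
        order = sorted(classes, key=lambda c: -(labels == c).sum())
        k = 0
        while diff != 0 and order:
            c = order[k % len(order)]
            if diff > 0 and per_class[c] < (labels == c).sum() - 1:
                per_class[c] += 1
                diff -= 1
            elif diff < 0 and per_class[c] > 1:
                per_class[c] -= 1
                diff += 1
            k += 1
            if k > 10 * len(order):  # infeasible target; keep the >=1-per-class floor
                break
        test_idx = set()
        for c in classes:
            members = np.flatnonzero(labels == c)
            chosen = rng.permutation(len(members))[:per_class[c]]
            test_idx.update(members[chosen].tolist())
    train_ids = [ids[i] for i in range(n) if i not in test_idx]
    test_ids = [ids[i] for i in range(n) if i in test_idx]
    return train_ids, test_ids
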