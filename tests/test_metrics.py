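"""Evaluation statistics against hand computations and reference oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, roc_auc_score)

from endoscreen.metrics import (UndefinedMetricError, accuracy, auprc, auroc,
                                balanced_accuracy, compute_report, dice,
                                patient_split, weighted_f1)


class TestWorkedExamples:
    def test_accuracy_counts_exact_matches(self):
        assert accuracy([0, 0, 1, 1], [0, 1, 1, 1]) == 0.75
        assert accuracy([0, 1], [0, 1]) == 1.0
        assert accuracy([0, 1], [1, 0]) == 0.0

    def test_weighted_f1_hand_case(self):
        # class 1: P=0.5, R=1 -> F1=2/3; class 0: F1=0; equal support
        assert weighted_f1([1, 1, 0, 0], [1, 1, 1, 1]) == pytest.approx(1 / 3)
        assert weighted_f1([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_weighted_f1_label_swap_invariance(self):
        y = np.array([0, 0, 1, 1, 1, 0])
        p = np.array([0, 1, 1, 0, 1, 0])
        assert weighted_f1(y, p) == pytest.approx(weighted_f1(1 - y, 1 - p))

    def test_auroc_pairwise_concordance(self):
        # positives (0.9, 0.4), negatives (0.5, 0.1): 3 of 4 pairs concordant
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        assert auroc(labels, scores) == pytest.approx(0.75)

    def test_auroc_extremes(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_auprc_step_sum(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        # threshold walk: 0.5*1 + 0.5*(2/3)
        assert auprc(labels, scores) == pytest.approx(0.8333, abs=1e-4)

    def test_auprc_all_ties_equals_prevalence(self):
        labels = np.array([1, 0, 0, 1, 0])
        scores = np.full(5, 0.3)
        assert auprc(labels, scores) == pytest.approx(0.4)

    def test_undefined_metrics_raise(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.raises(UndefinedMetricError):
            auprc([0, 0], [0.1, 0.2])


class TestOracleEquivalence:
    """All four metrics match the reference implementation to 1e-9 on
    random instances (100 draws)."""

    def test_random_instances_match_sklearn(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 60)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            preds = (scores >= 0.5).astype(int)
            assert accuracy(labels, preds) == pytest.approx(
                accuracy_score(labels, preds), abs=1e-9)
            assert weighted_f1(labels, preds) == pytest.approx(
                f1_score(labels, preds, average="weighted",
                         zero_division=0), abs=1e-9)
            assert auroc(labels, scores) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-9)
            assert auprc(labels, scores) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-9)


class TestInvariants:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_auroc_complement_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.permutation(n).astype(float)  # tie-free
        assert auroc(labels, scores) + auroc(labels, -scores) == pytest.approx(1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_ranking_metrics_monotone_transform_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.random(n)
        warped = np.exp(3 * scores) - 0.5  # strictly increasing
        assert auroc(labels, scores) == pytest.approx(auroc(labels, warped))
        assert auprc(labels, scores) == pytest.approx(auprc(labels, warped))


class TestDice:
    def test_identity_and_disjoint(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:5] = 1
        assert dice(m, m) == 1.0
        assert dice(m, np.zeros_like(m)) == 0.0
        assert dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0


class TestPatientSplit:
    def test_disjoint_exhaustive_and_sized(self):
        labels = {f"p{i}": int(i < 7) for i in range(10)}
        train, test = patient_split(labels, 0.2, stratify=True, seed=0)
        assert len(test) == 2 and len(train) == 8
        assert set(train) | set(test) == set(labels)
        assert set(train) & set(test) == set()

    def test_clinical_scale_cohort_rounding(self):
        # 116 patients at 20% -> 23 test / 93 train
        labels = {f"p{i}": int(i < 82) for i in range(116)}
        train, test = patient_split(labels, 0.2, stratify=True, seed=3)
        assert (len(train), len(test)) == (93, 23)

    def test_deterministic_in_seed(self):
        labels = {f"p{i}": i % 2 for i in range(20)}
        assert patient_split(labels, 0.2, seed=5) == patient_split(
            labels, 0.2, seed=5)
        assert patient_split(labels, 0.2, seed=5) != patient_split(
            labels, 0.2, seed=6)

    def test_stratified_keeps_minority_in_test(self):
        labels = {f"p{i}": int(i < 3) for i in range(20)}
        for seed in range(5):
            _, test = patient_split(labels, 0.2, stratify=True, seed=seed)
            assert any(labels[p] == 1 for p in test)

    def test_infeasible_stratification_raises(self):
        with pytest.raises(ValueError):
            patient_split({"a": 1, "b": 0}, 0.5, stratify=True, seed=0)
        # single patient in one class cannot be stratified
        with pytest.raises(ValueError):
            patient_split({"a": 1, "b": 0, "c": 0}, 0.3, stratify=True, seed=0)


def test_compute_report_fields(small_cohort):
    labels = [v.binary_label for v in small_cohort.videos]
    scores = np.linspace(0.1, 0.9, len(labels))
    rep = compute_report(labels, scores, level="patient")
    d = rep.as_dict()
    assert set(d) == {"accuracy", "weighted_f1", "auroc", "auprc",
                      "n_samples", "level"}
    assert all(0 <= d[k] <= 1 for k in ("accuracy", "weighted_f1", "auroc",
                                        "auprc"))
    assert d["n_samples"] == len(labels)


def test_balanced_accuracy_simple():
    assert balanced_accuracy([0, 0, 1, 1], [0, 0, 1, 0]) == pytest.approx(0.75)
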