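"""Shared fixtures.

Heavy artifacts (the trained weak labeler, the default synthetic cohort)
are session-scoped and shared across test modules so each is built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from endoscreen.synth import (SceneParams, generate_cohort,
                              generate_segmentation_set)
from endoscreen.weaklabel import train_unet


@pytest.fixture(scope="session")
def scene_params() -> SceneParams:
    """The default study conditions of the synthetic generator."""
    return SceneParams()


@pytest.fixture(scope="session")
def weak_labeler(scene_params):
    """Segmentation weak labeler trained at the study scale (1000 pairs,
    default training config); shared by the weak-labelling, quality-
    classifier and ablation tests."""
    pairs = generate_segmentation_set(scene_params, 1000)
    return train_unet(pairs)


@pytest.fixture(scope="session")
def default_cohort(scene_params):
    """Default synthetic cohort: 48 patients x 100 frames at 128x128."""
    return generate_cohort(scene_params, n_patients=48,
                           positive_fraction=0.7, frames_per_patient=100)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for structural (non-performance) tests."""
    return generate_cohort(SceneParams(seed=7), n_patients=6,
                           positive_fraction=0.5, frames_per_patient=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
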