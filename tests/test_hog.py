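"""HOG descriptors, cosine similarity, and the similarity filter."""

import numpy as np
import pytest

from endoscreen.core_data import FrameRecord, VideoRecord
from endoscreen.hog import (FilterParams, HogParams, compute_hog,
                            cosine_similarity, similarity_filter)
from endoscreen.synth import SceneParams, generate_video


def _frame(pixels, idx=0, pid="p0"):
    return FrameRecord(pid, idx, pixels.astype(np.float32))


def _video(frames_pixels, grade=1):
    frames = [_frame(px, i) for i, px in enumerate(frames_pixels)]
    return VideoRecord("p0", frames, grade)


class TestComputeHog:
    def test_default_descriptor_length_is_26244(self):
        # 224/8=28 cells, 27x27 blocks of 2x2 cells x 9 bins
        params = HogParams()
        assert params.descriptor_length == 27 * 27 * 2 * 2 * 9 == 26244
        img = np.random.default_rng(0).random((224, 224, 3)).astype(np.float32)
        assert len(compute_hog(_frame(img), params)) == 26244

    def test_constant_frame_gives_zero_descriptor(self):
        d = compute_hog(_frame(np.full((64, 64, 3), 0.3)),
                        HogParams(resize_to=(64, 64)))
        assert np.all(d.values == 0)

    @pytest.mark.parametrize("axis", [0, 1])
    def test_step_edge_energy_in_brute_force_bin(self, axis):
        """>= 90% of descriptor energy falls in the orientation bin holding
        the step edge's gradient, located independently by centred
        differences on the toy image."""
        params = HogParams(resize_to=(64, 64))
        img = np.zeros((64, 64, 3), dtype=np.float32)
        if axis == 0:
            img[32:, :] = 1.0  # horizontal edge -> vertical gradient
        else:
            img[:, 32:] = 1.0  # vertical edge -> horizontal gradient
        gray = img[..., 0]
        gy, gx = np.gradient(gray)
        mag = np.hypot(gx, gy)
        angles = np.rad2deg(np.arctan2(gy, gx)) % 180
        dominant = angles[mag > 0][np.argmax(mag[mag > 0])]
        expected_bin = int(dominant / 180 * params.n_bins) % params.n_bins
        energies = (compute_hog(img, params).values.reshape(-1, 9) ** 2).sum(axis=0)
        assert energies[expected_bin] / energies.sum() >= 0.9

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(3)
        img = (0.5 * rng.random((64, 64, 3))).astype(np.float32)
        p = HogParams(resize_to=(64, 64))
        a = compute_hog(_frame(img), p).values
        b = compute_hog(_frame(img + 0.25), p).values
        assert np.allclose(a, b, atol=1e-6)

    def test_resize_must_divide_cell_size(self):
        with pytest.raises(ValueError):
            HogParams(resize_to=(100, 100), cell_size=8)


class TestCosineSimilarity:
    def test_identity_orthogonal_and_hand_value(self):
        assert cosine_similarity([1, 0, 1], [1, 0, 1]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0, 1], [0, 1, 0]) == 0.0
        # dot=1, norms sqrt(2)*sqrt(2) -> 0.5
        assert cosine_similarity([1, 0, 1], [1, 1, 0]) == pytest.approx(0.5)

    def test_zero_vector_convention_and_mismatch(self):
        assert cosine_similarity([0, 0], [1, 2]) == 0.0
        with pytest.raises(ValueError):
            cosine_similarity([1, 2], [1, 2, 3])

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(30), rng.random(30)
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity(a, 7.3 * b) == pytest.approx(
            cosine_similarity(a, b))
        assert -1 <= cosine_similarity(a - 0.5, b - 0.5) <= 1


class TestSimilarityFilter:
    def test_identical_frames_collapse_to_index(self):
        img = np.random.default_rng(1).random((64, 64, 3)).astype(np.float32)
        video = _video([img] * 10)
        kept = similarity_filter(video, HogParams(resize_to=(64, 64)),
                                 FilterParams(tau_rel=0.5, tau_dup=0.98))
        assert kept == [0]

    def test_permissive_thresholds_keep_everything(self):
        rng = np.random.default_rng(2)
        video = _video([rng.random((64, 64, 3)) for _ in range(6)])
        kept = similarity_filter(video, HogParams(resize_to=(64, 64)),
                                 FilterParams(tau_rel=-1.0, tau_dup=1.0))
        assert kept == list(range(6))

    def test_output_strictly_increasing_and_deterministic(self):
        rng = np.random.default_rng(3)
        video = _video([rng.random((64, 64, 3)) for _ in range(8)])
        p, f = HogParams(resize_to=(64, 64)), FilterParams(tau_rel=0.3)
        kept = similarity_filter(video, p, f)
        assert kept == sorted(set(kept))
        assert kept == similarity_filter(video, p, f)

    def test_retained_count_monotone_in_tau_rel(self):
        """With the redundancy check disabled, raising the relevance
        threshold can only shrink the retained set."""
        rng = np.random.default_rng(4)
        video = _video([rng.random((64, 64, 3)) for _ in range(10)])
        p = HogParams(resize_to=(64, 64))
        counts = [len(similarity_filter(video, p,
                                        FilterParams(tau_rel=t, tau_dup=1.0)))
                  for t in (-1.0, 0.0, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_relevance_gate_separates_disjoint_structure(self):
        """Frames sharing the index frame's edge structure pass the
        relevance gate; structureless (flat) frames and frames with
        orthogonal orientation content fail it (checked over seeds).

        Note: the block-normalised descriptor saturates on dense natural
        texture, so scene-level structure — not texture statistics — is
        what the gate can discriminate.
        """
        p = HogParams(resize_to=(64, 64))
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = np.zeros((64, 64, 3), dtype=np.float32)
            base[:, ::8] = 1.0  # vertical stripes: one orientation family
            relevant = [np.clip(base + 0.02 * rng.standard_normal(base.shape),
                                0, 1) for _ in range(10)]
            flat = [np.full((64, 64, 3), rng.random(), dtype=np.float32)
                    for _ in range(5)]
            ortho = [np.ascontiguousarray(np.transpose(f, (1, 0, 2)))
                     for f in relevant[:5]]
            video = _video(relevant + flat + ortho)
            kept = similarity_filter(video, p, FilterParams(tau_rel=0.5,
                                                            tau_dup=1.0))
            assert all(i < 10 for i in kept), "an irrelevant frame survived"
            assert len(kept) >= 0.8 * 10

    def test_empty_video_and_bad_index(self):
        img = np.zeros((64, 64, 3), dtype=np.float32)
        video = _video([img, img])
        with pytest.raises(ValueError):
            similarity_filter(video, HogParams(resize_to=(64, 64)),
                              FilterParams(index_frame=5))
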