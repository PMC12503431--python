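# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package. It describes what the code does and why; every
number quoted here is recomputed by the test suite or the scripts — nothing
is asserted from memory.

## Problem setting

A flexible nasopharyngoscopy (FNS) examination produces a frame sequence of
which only a minority shows the glottis sharply and completely; the rest is
blurred by motion, hazed or occluded by secretions, or aimed elsewhere. The
screening task is patient-level binary triage — referral (grades 2–3)
versus no referral (grade 1) — from such a sequence. The package's model of
this task has two stages: an image quality module (IQM) that selects usable
frames, and a disease classification module (DCM) whose per-frame referral
probabilities are averaged into the patient decision.

## Synthetic data generator

Because the underlying clinical corpora are private, the generator emulates
their structure rather than their appearance:

* **Scene.** A pink, low-frequency tissue texture with mild vignetting; the
  glottis is a dark, soft-edged ellipse (aspect 2.2–3.2, orientation jitter
  ±25°) whose area is `glottis_area_fraction` (default 0.05) of the frame,
  jittered ±25%; the exact interior is the ground-truth mask.
* **Patient style.** Every video has a persistent appearance: one tissue
  field and one illumination tint (channel gains ±7%, brightness ±0.04)
  shared by all of its frames. This mirrors real video — the same anatomy,
  endoscope and lighting throughout an exam — and it is load-bearing: a
  classifier trained on degradation-dominated sequences can only latch
  onto such patient-specific appearance, which does not generalise to new
  patients. Without this correlation, degraded frames would be independent
  noise that cancels in the patient-level mean and quality filtering would
  have nothing to improve.
* **Disease signal.** Referral-positive patients carry a lesion: a
  zero-mean luminance speckle (correlation length ≈ 2.5 px at 128 px)
  painted in a soft disc adjacent to the glottis, contrast
  `lesion_strength` (default 0.15; grade 3 is 1.5× grade 2, cosmetic since
  the task is binary). The speckle is a *texture*: it survives moderate
  downsampling but is erased by the blur of degraded frames, so only
  good-quality frames carry usable signal. The default contrast is
  deliberately subtle — calibrated so that frame-level classification is
  learnable from clean frames but not from degradation-dominated
  sequences, the regime in which a quality filter has measurable value.
  With `lesion_strength = 0` positive and negative renderings are
  pixel-identical (a built-in null).
* **Degradations.** Each poor frame is off-target (no glottis; probability
  0.25), blurred (σ ∈ [3, 6] px plus a 35% blend toward a bright haze —
  secretions both blur and de-contrast real frames), or occluded by a
  bright secretion-like blob (≈30% of the frame, centred near the glottis).
  All frames get mild sensor noise (σ = 0.008).
* **Composition.** `good_frame_fraction` defaults to 0.15: clinical IQM
  studies retain on the order of one good frame in ten from raw FNS video,
  and at substantially higher fractions the disease signal survives
  unfiltered sequences, leaving a quality filter nothing to improve. The
  realized good count is exact (`round(fraction × n_frames)`), frame 0 is
  always good (it serves as the similarity index frame), and cohorts assign
  `round(positive_fraction × n)` patients to grades 2–3 (default 0.7,
  matching the roughly 70/30 referral mix of triage cohorts).
* **Determinism.** All randomness derives from one master seed through
  `SeedSequence`; a cohort is reproducible byte for byte.

What the generator does **not** emulate: camera trajectories and temporal
correlation between frames, specular highlights, anatomical variability,
multi-class pathology appearance, and realistic colour statistics. Passing
tests therefore demonstrate that the pipeline's machinery works and that
its stages compose correctly under controlled signal/noise conditions —
not clinical performance.

## HOG similarity filtering

Frames are summarised by the canonical descriptor (grayscale, resize to
224², 8-px cells, 2×2-cell blocks, 9 unsigned orientation bins, magnitude
weighting, per-block L2 normalisation) and compared by cosine similarity to
an operator-chosen index frame. Two thresholds: keep a frame iff similarity
to the index ≥ `tau_rel` (relevance; default 0.5) and similarity to the
most recently retained frame < `tau_dup` (redundancy; default 0.98,
disabled at ≥ 1). Ties: ≥ keeps at the relevance gate, ≥ drops at the
duplicate gate. A flat frame has an all-zero descriptor and similarity 0 by
convention.

**Known limitation.** Per-block normalisation makes every textured block a
unit vector, so cosine similarity between any two texture-rich frames
saturates near 0.7 regardless of content; on the synthetic scenes the
relevance gate reliably rejects only structureless frames or frames with
disjoint orientation content. The supervised quality classifier, not the
HOG gate, carries the main filtering burden — which is also how the
two-stage design apportions the work. The pipeline default for the
end-to-end run therefore sets a permissive `tau_rel` (0.2) and treats the
HOG stage primarily as a redundancy/relevance pre-filter.

## Weak labelling

A U-Net (depth 3, 8 base channels, 64×64 input, two 3×3 conv+BN+ReLU per
level, nearest-neighbour upsampling, BCE + soft-Dice loss, Adam, 6 epochs)
is trained on synthetic benchmark-style pairs. These sizes are deliberately
small — they train in minutes on one CPU core and reach held-out Dice
≈ 0.95 on the synthetic scenes; a full-scale U-Net would add nothing here.

**Quality-abstention augmentation.** Training on sharp pairs alone produces
a segmenter that happily finds blurred or half-occluded glottises, which
defeats quality labelling. Half again as many training samples (ratio
`degrade_fraction` = 0.5) are therefore degraded copies — blur+haze, or a
secretion blob painted over the glottis — paired with an *empty* mask,
teaching the network to abstain when the glottis is not sharply and
entirely visible. This is the mechanism that makes the downstream criteria
meaningful; without it, weak-label balanced accuracy against generator
truth drops from ≈0.99 to ≈0.8.

A frame is labelled *good* iff the thresholded prediction (p ≥ 0.5) has
area ≥ `min_area_fraction` (0.002) of the frame and no mask pixel within
`border_margin` (2 px) of the frame edge — an operational reading of "the
glottal area is entirely visible".

## Quality classifier and frame selection

The default quality classifier is the reduced-width baseline CNN (widths
8-8-16-16-32-32) at 32×32 input: quality cues (haze, missing dark region,
bright occluder) are low-frequency, so a small input suffices, and training
on a full cohort takes seconds. Selection keeps frames with score ≥ 0.5,
ranked by descending score (ties by ascending frame index), truncated to
the frame budget `max_n`; a video with fewer than `min_frames` (default 10)
selected frames is flagged excluded, mirroring how studies drop videos with
insufficient usable footage.

## Disease classifier and aggregation

Frames inherit the patient label. The desk-scale DCM is the reduced
baseline CNN at 64×64 — enough resolution to resolve the lesion speckle
after 2× downsampling. Training uses prevalence-corrected cross entropy by
default (weights n/(2n_c)); with a 70/30 cohort an unweighted model drifts
toward all-positive predictions and the 0.5 decision threshold becomes
meaningless. The harness gives every condition the same optimisation
budget — about 1800 frame-passes at batch 32 with Adam (lr 2e-3), i.e.
more epochs on smaller filtered sets — so conditions differ by the quality
of their data, not by training effort. The harness also calibrates the
decision threshold per condition on training-patient aggregates (balanced
accuracy, midpoint candidates); `predict_patient` itself keeps the plain
0.5 default. Published triage studies rarely state their operating point,
and with small desk-scale models the raw 0.5 threshold is an uncalibrated
coin flip that would disconnect accuracy from ranking quality. Binary focal loss (−α(1−p_t)^γ log p_t, γ = 2, α = 0.25,
constant α as the formula states; γ = 0, α = 1 recovers cross entropy) is
implemented and selectable; the ablation harness does not use it by
default. The patient-level probability is exactly the arithmetic mean of
the frame probabilities — "bootstrap aggregation" in the sense of bagging
frame-level predictions, with no resampling — thresholded at 0.5.

Patient-level splits are stratified 80/20 (test size `round(0.2 n)`, at
least one patient per class) and a leakage guard raises if any patient
appears on both sides.

## Architecture cost accounting

All four backbones are layer graphs in the package's own NumPy backend, so
FLOP accounting is an analytic walk over the same objects that compute
forward passes: 1 MAC = 1 FLOP; convolutions count
C_in/g · C_out · k_h · k_w · H_out · W_out, linear layers in·out;
normalisation, activations, pooling and the squeeze-excite poolings count
zero (the SE fully-connected layers are counted). Under this convention at
224×224 and batch 64 the package computes ResNet50 ≈ 262, MobileNetV2 ≈ 19,
GhostNet ≈ 9 GFLOPs — within the ±10% spread that separates published
counting conventions, and reproducing the efficiency ordering
GhostNet < MobileNetV2 < ResNet50 (computed ratio ResNet50/GhostNet ≈ 29×).
The 6-layer baseline's cost depends entirely on its (unpublished) channel
widths, so no external figure is targeted for it. Wall-clock inference
timing is reported for relative comparison only and is never a test target.

## Ablation harness

`run_experiment` evaluates the DCM under: no quality filtering ("none");
filtering with per-patient budgets n = 10, 30, 50; and "unlimited" (all
accepted frames). Per seed it redraws the patient split and retrains the
IQM (on weak labels of training patients only) and the DCM per condition.
Desk-scale budgets: per-patient training frames are capped at 50
(top-scoring under filtering, a seeded random subset under "none");
problem size defaults to 48 patients × 100 frames at 128×128 over 5 seeds.
Patient-level accuracy, weighted F1, AUROC and AUPRC are reported per seed
and as seed means.

## Evaluation metrics

Implemented from their definitions so they are auditable: accuracy (exact
match fraction); weighted F1 (per-class F1 weighted by true support, 0 for
a class never predicted correctly); AUROC as the Mann–Whitney statistic
(average ranks, ties ½); AUPRC as average precision (step interpolation,
tied scores entering as one group). Undefined cases (single-class AUROC,
no positives for AUPRC) raise rather than returning a default. Tests
verify agreement with both independent brute-force computations and
scikit-learn to 1e-9.

## Numerical choices

float32 throughout; Adam (β = 0.9/0.999, ε = 1e-8); He-normal
initialisation; probability clipping at 1e-7 in losses; BN ε = 1e-5 with
momentum 0.1; seeded shuffling and dropout share one generator per fit, so
training is bit-reproducible on a fixed BLAS. Mask binarisation at 0.5 of
full range; nearest-neighbour mask upsampling; block-mean downsampling for
integer factors, anti-aliased resize otherwise.

## Known limitations

* The NumPy backend is single-threaded-BLAS CPU code: fine at the package's
  default sizes, not for 224² training. Wall-clock comparisons between
  architectures are dominated by Python-level layer overhead, so they are
  informational only.
* The HOG relevance gate is weakly discriminative on texture-rich synthetic
  content (see above).
* Weak labels are near-perfect on synthetic scenes; on real video the
  segmentation model would face domain shift the synthetic tests cannot
  measure.
* Grades 2 and 3 differ only in lesion contrast; nothing in the pipeline
  distinguishes them (the task is binary by design).
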