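# Methods

This document describes the algorithms, the default parameters and the
reasoning behind them, module by module. Conventions throughout: images are
float64 arrays in `[0, 1]` with dark structures on a light background,
coordinates are 0-based `(row, col)`, boxes are half-open
`(row0, col0, row1, col1)`, angles are degrees counter-clockwise from the
+col axis, and `a`/`b` denote **semi**-major/minor axis lengths in pixels.
The default image resolution is 8.6 px/µm (`stomapore.io.DEFAULT_PIXEL_SCALE`).

## 1. Synthetic scene generator (`stomapore.synth`)

A scene emulates an epidermal-imprint micrograph: elliptical stomatal pores
bounded by a dark ring and a brighter guard-cell annulus, a background
textured by polygonal cell walls, plus vein-like curvilinear ridges and dust
blobs as distractors, finished with Gaussian blur (σ = 0.9 px) and additive
Gaussian noise (sd = 0.025, clipped to `[0, 1]`). All randomness flows from
the single `SceneSpec.seed` through one `numpy` generator, so equal specs
render byte-identical scenes.

Default study conditions (`SceneSpec`): 768×768 px, 8 stomata per scene,
pore semi-major axis `U(12, 35)` px, aspect ratio `b/a ∈ U(0.55, 0.90)`
(eccentricity ≈ 0.44–0.84), random orientation, centers rejection-sampled
to pairwise separation ≥ 110 px (failure raises `RuntimeError` naming the
constraint), 3 veins and 10 dust blobs.

Image quality is bimodal, mirroring real imprint series: half the stomata
(`complete_fraction = 0.5`) are rendered in-focus — complete boundary ring,
dark interior (level 0.20) — and the rest are degraded: the ring is drawn
only over a contiguous arc whose angular fraction is the drawn
`completeness ∈ U(0.65, 0.90)` and the interior washes out to 0.58, close
to the background. The washed-out interior is what defeats a global
threshold and routes these stomata to the skeleton measurement path; the
generator therefore exercises both morphometry paths by construction.

Rendering details that matter downstream:

- the 3-px boundary ring is drawn **inside** the pore ellipse, so a complete
  stoma thresholds to exactly the filled pore ellipse — ground-truth area is
  `π·a·b` with no ring correction;
- gray levels are well separated (`RenderPalette`: pore ring 0.10, sharp
  interior 0.20, veins/dust 0.18–0.20, walls 0.60–0.64, background 0.72,
  guard cells 0.84) so Otsu thresholds land between the dark-structure and
  wall populations on realistic scenes;
- ground truth per stoma: center, pore ellipse, completeness, orientation
  (`ground_truth_frame` serializes this to CSV).

`make_training_set` crops window-sized positives centered on planted
stomata and negatives from stoma-free scenes (veins, dust and walls only),
each from its own seeded scene stream.

## 2. HOG features (`stomapore.hog`)

Standard rectangular HOG: central-difference gradients, orientation folded
to `[0°, 180°)`, magnitude-weighted soft binning into 9 bins over 8×8-px
cells, contrast normalization over 2×2-cell blocks with L2 norm + ε
(`1e-6`), blocks overlapping by one cell. For the 96×96 detector window
that is 12×12 cells → 11×11 blocks → **4356 features**. A constant window
yields the zero vector (the ε keeps normalization finite); rotating a
pattern by 90° permutes the orientation bins by `n_bins/2`, which the tests
use as an oracle.

`CellHogGrid` computes the cell histograms of a full image once and lets
the detector read any window's feature vector, or a single feature
component, without recomputing gradients — this is what makes cascade
early-exit pay off. It also maintains a summed-area table of per-cell
gradient energy; `window_energies` returns each window's total energy in
O(1).

## 3. Boosted cascade (`stomapore.cascade`)

Each stage is a discrete-AdaBoost ensemble of decision stumps, one HOG
component per stump (threshold + polarity chosen by weighted error over a
candidate feature subsample). After boosting, the stage threshold is
**lowered** until the stage passes ≥ 99.5% of training positives
(`stage_tpr_min`); a stage must reach false-positive rate ≤ 0.5
(`stage_fpr_max`) on its negatives, adding stumps (up to 64) until it does.
A window is accepted only if every stage accepts; each stage rejection
ends evaluation immediately, so the expected cost per background window is
a handful of stump lookups.

`train_cascade` bootstraps: stage *k* trains on the original positives and
on negatives that survive stages 1..k−1, mined from the negative pool (up
to 800 per stage). When fewer than 10 surviving negatives can be found the
pool is exhausted — every training negative is already rejected — and
training stops early with a `UserWarning`, returning fewer stages than
requested. This is expected on clean synthetic data (typically 2–4 strong
stages out of 8 requested).

`min_weak_learners_schedule = (4, 8, 12, …)` forces deeper stages to boost
past the point where the FPR target is already met. Rationale: late stages
see few, hard negatives; without a floor they would fit one or two stumps
to the exact bootstrap sample and generalize poorly to distractor
configurations (vein angles, wall junctions) not present verbatim in it.

Detection (`detect`): image pyramid at scales `(0.86, 1.12, 1.45, 1.89,
2.45)` (window side / scale covers pore diameters across the generator's
size range), stride 8 px (= one HOG cell, so windows reuse the cell grid
exactly), zero-gradient-energy windows dropped up front (a featureless
window cannot contain a stoma, and an all-zero feature vector would
otherwise be at the mercy of stump polarities), score = sum of stage
margins. Non-maximum suppression greedily keeps the highest-scoring boxes,
discarding boxes with IoU > 0.3 against a kept box; an additional pass
suppresses boxes whose center lies inside a kept box (concentric
multi-scale responses that survive the IoU test). Models serialize to
versioned JSON (`"format": "stomapore-cascade"`) with byte-identical
round-trip.

## 4. Pore morphometry (`stomapore.morphometry`)

Input: an ROI around a detection (pipeline crops 1.3× the detection box)
plus a `PoreConfig`. Output: a frozen `PoreMeasurement` with
status `measured`/`discarded`, method `segmentation`/`skeleton`, area
(px² and µm²), eccentricity, **full** axis lengths `2a`/`2b`, and a machine-
readable `reason` when discarded. Discarded measurements carry no numeric
fields (enforced in `__post_init__`): a number that is known to be wrong is
worse than no number.

**Binarization.** Unsharp masking (amount 1.0) then a global Otsu
threshold, dark side = foreground. Otsu is parameter-free and behaves well
on the bimodal dark-structure/background histograms of realistic ROIs.

**Segmentation path.** Among connected components (8-connectivity) with
area inside `[area_min_px, area_max_px]`, pick the one whose centroid is
nearest the ROI center; accept it only if its *fill ratio* — pixel count
over the area `π·a·b` of its own moment-equivalent ellipse — is ≥ 0.85. A
filled pore ellipse passes; a thin boundary arc or a vein fragment of
similar pixel count fails, which is the trigger for the skeleton path.
Eccentricity comes from second central moments; a degenerate 1-px region
gets `E = 0`.

**Skeleton path.** The binary image is thinned (`skimage.skeletonize`),
spurs shorter than 5 px are pruned by walking from each endpoint and
deleting the walk if a branch point is reached (`prune_spurs`), and the
remnant is selected by path length within `skeleton_length_bounds` and
centroid distance to the ROI center. Its pixels are fitted with the direct
least-squares ellipse method (numerically stable algebraic fit; via
`skimage.measure.EllipseModel`). The fit must pass three confidence gates,
any failure raising `EllipseFitError` → measurement discarded:

1. *elliptic conic* — the solver must return a finite ellipse at all;
2. *angular coverage* ≥ `min_completeness = 0.6`: the largest gap in the
   points' parametric angles may span at most 40% of the ellipse. Below
   half an arc the algebraic fit is notoriously unstable (the tests verify
   ≥ 80% rejection for sub-50% noisy arcs while clean 65% arcs recover
   axes within 5%);
3. *radial residual*: the mean of `|ρ − 1|` over the points' normalized
   radial coordinates must be ≤ `max_fit_residual = 0.1`. This rejects
   skeletons that are not boundary arcs at all — e.g. the blob-like
   skeleton of a wall fragment, around which a small ellipse can satisfy
   gate 2 while fitting nothing. Measured distributions on synthetic ROIs:
   genuine arcs ≈ 0.02 mean residual, blob skeletons ≈ 0.2; the 0.1
   threshold sits between the populations rather than on a test boundary.

The accepted ellipse, dilated by 3 px (tolerance for the fit landing on
the ring's inner edge), masks the ROI; dark pixels under the global
threshold are kept and the remaining masked pixels are re-thresholded with
a **local** Otsu — this recovers the washed-out interior, whose levels the
global threshold lumped with background. The largest in-bounds region is
then measured exactly as in the segmentation path, so both paths report
the same quantities with the same estimator.

**Axis lengths (Eqs 1–2).** From measured area `A` and eccentricity `E`:

    a = sqrt(A / (π·sqrt(1 − E²)))        b = sqrt(A·sqrt(1 − E²) / π)

These satisfy `π·a·b = A` and `b/a = sqrt(1 − E²)` identically (verified
to 1e−9 over random `(A, E)`), i.e. the reported ellipse reproduces the
measured area exactly rather than the moment ellipse's area.

**Per-ROI sizing.** `pore_config_for_box` scales the bounds to the
detection-box side `w`: pore area ∈ `[0.08·w², 0.45·w²]`, skeleton length
∈ `[0.6·w, 2.6·w]`. The constants come from geometry, not tuning: a pore
ellipse with the generator's aspect range occupies roughly 10–40% of its
bounding box, and a boundary arc's length is between ~⅔ of the pore
perimeter and the full perimeter ≈ `π·w`. Configs created directly get
conservative defaults via `PoreConfig.resolved_for(roi_shape)`.

## 5. Metrics (`stomapore.metrics`)

Matching is one-to-one and greedy by center distance: each ground-truth
center may match the nearest unmatched detection whose box contains it;
pairs are consumed nearest-first. Matched = TP, spare detections = FP,
unmatched truths = FN. On non-overlapping boxes the greedy matching is
optimal; `match_detections` returns the `ConfusionCounts`,
`match_detection_indices` additionally exposes the pairing for the
pipeline's per-stoma agreement.

From counts: precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, accuracy as the
critical-success-index `TP/(TP+FP+FN)` (stricter than precision and recall
— it has no true-negative term, which is the appropriate choice for
detection where "true negative windows" are uncountable), and F1. All-zero
counts warn and return zeros; `pore_identification_rate(n_measured,
n_discarded)` raises on an empty total.

Measurement agreement (Eq 3) against ground truth `Y` and estimate `Ŷ`:
`agreement% = 100 − |(Y − Ŷ)/Y|·100` — the complement of the relative
error, so 100 means exact. Display rounding uses decimal half-up
(`round_half_up`, 2 dp), not banker's rounding, to match the published
worked examples (e.g. `.005 → .01`).

## 6. Pipeline and synthetic study (`stomapore.pipeline`)

`run_end_to_end(model, micrograph)` detects (defaults in `DetectConfig`:
stride 8, study scales, NMS IoU 0.3), crops each detection with 1.3×
margin, builds the per-ROI `PoreConfig`, measures, and returns
index-aligned detection and measurement lists; `detections_frame` /
`measurements_frame` serialize both to CSV.

`run_synthetic_study(seed, n_pos=200, n_neg=100, n_scenes=20)` derives
independent training and evaluation streams from a `SeedSequence` (so one
31-bit user seed reproducibly yields all scene seeds), trains a cascade on
200/100 window patches, evaluates on 20 fresh default-spec scenes (160
planted stomata), matches detections to truth, and reports detection
metrics, measured fraction, and mean Eq-3 agreement of pore area
(separately per measurement path) and eccentricity over matched true
positives only — false positives have no ground truth to agree with.

Reference results (seed 1, single CPU, ~35 s total: train ≈ 13 s, detect
≈ 16 s, measure ≈ 1 s): precision 94.67%, recall 100.00%, 95.27% of ROIs
measured; area agreement 99.63% on the segmentation path (n = 80) and
95.30% on the skeleton path (n = 79); eccentricity agreement 98.41%. The
gap between the paths is expected: the skeleton path reconstructs the pore
from a partial boundary of a deliberately degraded stoma.

## 7. Numerical and testing notes

- All stochastic code takes explicit integer seeds (< 2³¹) or
  `numpy.random.Generator`s; nothing reads global RNG state.
- Ellipse fitting uses the algebraic direct-least-squares formulation; the
  exact-recovery tests tolerate 1e−6 relative error on noiseless points.
- The test suite (~160 tests, ≈ 1 minute) contains per-module unit and
  property tests (including `hypothesis` properties for metric
  conservation laws and NMS invariants) and an acceptance layer asserting:
  the published metric worked examples, the Eq 1–2 identities, ellipse-fit
  recovery/rejection behavior, skeletonization oracles (idempotence on
  1-px curves; rectangle medial-axis length `w − h + 1` within 2 px), and
  the end-to-end study bars (precision ≥ 85, recall ≥ 75, ≥ 85% measured,
  area agreement ≥ 95 segmentation / ≥ 85 skeleton, eccentricity ≥ 97).
- `scripts/acceptance.py --seed S --out report.json` re-runs the worked
  examples and the full study and writes every headline quantity with its
  sample size to JSON.
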