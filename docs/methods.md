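# Methods

## Problem and pipeline

The package screens for anemia from photographs of the everted lower eyelid.
Physiologically, low hemoglobin reduces capillary perfusion of the palpebral
conjunctiva, which pales from saturated vascular red toward pink. The
pipeline turns that sign into a three-class decision (anemic / moderately
anemic / normal) in four stages: ROI detection, color segmentation, feature
extraction, MLP classification; a fifth, optional stage aggregates geotagged
predictions into prevalence maps.

## Gold-standard labeling

Labels come from the subject's Hb concentration (g/dL), graded with
sex-specific cutoffs:

| class    | male              | female            |
|----------|-------------------|-------------------|
| anemic   | Hb < 10.5         | Hb < 10.5         |
| moderate | 10.5 ≤ Hb ≤ 13.5  | 10.5 ≤ Hb ≤ 12.0  |
| normal   | Hb > 13.5         | Hb > 12.0         |

Boundary values are assigned to the moderate band (closed interval); the
strict alternative would only move sets of measure zero. Hb values outside a
(0, 25) g/dL plausibility window are rejected rather than graded.

## ROI detection (baseline)

The baseline detector thresholds CIELAB *a\** (green–red axis) at the larger
of the image's 80th percentile and an absolute floor of 5 (gray pixels have
|a*| < 0.5, so the floor makes noisy achromatic images fail detection instead
of boxing noise). Because a percentile threshold always passes isolated noise
pixels, the detector keeps only the largest 8-connected component of passing
pixels and returns its tight bounding box padded by a configurable margin
(pipeline default 12 px). This is deliberately a *baseline*: a trained object
detector can replace it by supplying boxes in the documented CSV format.

## Segmentation

K-means (Lloyd's algorithm) clusters the ROI pixels in the (a\*, b\*) chroma
plane; L\* is excluded because it mostly encodes illumination while chroma
carries the tissue distinctions. Defaults and numerical choices:

* k = 3 (conjunctiva, sclera, skin are the three chromatic materials in a
  well-framed eyelid photograph); configurable.
* k-means++ initialization; 8 restarts drawn from one seeded generator, the
  restart with the lowest final objective wins (ties: first). Restarts are
  load-bearing: the conjunctiva is small but chromatically extreme, so a
  single k-means++ draw sometimes places two seeds inside it and Lloyd then
  converges to a local optimum that splits it in half.
* Stopping: assignment fixed point, or 300 iterations. The per-iteration
  objective (sum of squared distances) is recorded and is non-increasing.
* Empty clusters are re-seeded to the point farthest from its assigned
  centroid.
* Identical seeds give bit-identical models.

The conjunctiva mask is the cluster with maximum centroid a\* (redness is the
physiologically relevant axis); exact ties break toward the larger cluster,
then the lower index. External single-channel PNG masks (nonzero =
foreground) bypass this stage.

## Features

Seven scalars on the masked pixel multiset; all are permutation-invariant
and deterministic. Grayscale intensity is (R+G+B)/3, consistent with HSI
intensity. Standard deviation uses divisor N (population). Entropy uses the
256-bin histogram of half-up-rounded intensity, in bits. HSI follows the
arccos (Gonzalez–Woods) formulation with H ∈ [0, 360), S = 0 ⟹ H = 0.

Two thresholds are genuinely free parameters and are exposed as
configuration:

* **τ_H = 300°** (high-hue ratio): hues in [300°, 360°) form the magenta–red
  band adjoining pure red at 360°/0°; vascular tissue with B slightly above
  G lands there, pale or yellowish tissue does not.
* **δ = 70** (red pixel percentage, 8-bit counts): a pixel is "red" when
  R − max(G, B) ≥ δ. The margin is set high enough to demand saturated
  vascular red: a mild warm cast (skin, pale mucosa, warm illumination)
  carries red dominance of 30–55 levels, so a small margin would count
  nearly every pixel of any conjunctiva — healthy or pale — as red and the
  feature would saturate at 1.0 for all classes. At δ = 70 the feature
  grades the *degree* of pallor: saturated red tissue (separation ≳ 90)
  scores ~1, moderately pale tissue scores intermediate, markedly pale
  tissue scores near 0.

Feature vectors on regions smaller than 50 px are refused (flagged, not
imputed): sliver statistics are unreliable.

## Classifier and evaluation

A scikit-learn pipeline: `StandardScaler` followed by an MLP with one hidden
layer of 25 ReLU units, softmax output, at most 1000 iterations. The solver
is L-BFGS: on a 7-feature, ~600-sample problem it is faster and more stable
than stochastic optimizers and is deterministic, so identical seeds give
identical models and duplicating the training rows leaves the fitted optimum
unchanged (the mean loss surface is identical).

Evaluation uses a stratified 90/10 split with per-class half-up rounding of
the test count (611 images with class mix 132/169/310 → 550 train / 61
test). Resubstitution metrics (the training data scored by its own model)
are the convention in this screening literature but are optimistically
biased, so the held-out metrics are always computed and reported alongside
them — consumers should quote the held-out numbers.

Metrics are one-vs-rest per class: accuracy, precision (= PPV), sensitivity,
specificity, F1, FDR; macro values are unweighted class means and overall
accuracy is trace/total. Ratios with zero denominators (e.g. PPV of a class
never predicted) are NaN with a warning, never silently zero. One-vs-rest
AUC uses the rank (Mann–Whitney) statistic with average ranks, so score ties
contribute ½; this equals trapezoidal integration of the exhaustive-threshold
ROC, which the tests verify.

## Synthetic data generator

The generator emulates the statistical structure of a pallor-screening study
dataset so every stage is testable without clinical images:

* **Scale**: 611 images — 132 anemic, 169 moderate, 310 normal; sex drawn
  with the study ratio 24 male : 30 female; Hb sampled uniformly inside the
  class × sex grading interval (anemic lower bound 6.0; normal upper bounds
  17.5 male / 15.5 female, the textbook normal ranges), so
  `label_from_hb(sex, hb) == label` holds by construction.
* **Scene**: 256×256 px; skin background (206, 176, 128), pale sclera
  ellipse (242, 238, 225), lower-lid conjunctiva crescent covering 3–15 % of
  the image (≈ 8 % at defaults). Geometry and region mean colors get small
  per-image jitter (±4 px, color σ = 3), then i.i.d. Gaussian pixel noise
  (σ = 8) and a mild vertical illumination gradient (×1.05 top → ×0.95
  bottom). The skin tone is deliberately yellower than the conjunctiva
  (higher b\*, low a\*), as real skin is relative to mucosa; this keeps the
  three materials resolvable in the chroma plane at the chosen noise level.
* **Class color model**: conjunctiva means normal (190, 60, 72), moderate
  (195, 100, 105), anemic (200, 125, 127). Two properties were designed in,
  once, from the feature definitions: (i) the red–green separation falls
  130 → 95 → 75 across the δ = 70 red-pixel threshold, so mean RPP decreases
  strictly with severity rather than saturating for every class; (ii) the
  blue excess over green falls 12 → 5 → 2, so the fraction of pixels whose
  hue lands in the ≥ 300° magenta band (HHR) decreases strictly as well.
  A constant "very red" color for all classes would defeat both features —
  the generator encodes pallor as the features measure it.
* **Lighting**: six white-balance presets (tungsten, cloudy, daylight =
  identity, flash, fluorescent, shade) as per-channel gains with half-up
  rounding and clipping; "all" expands a manifest six-fold (611 → 3,666).
  Augmented manifest rows reference the base render plus their preset name;
  pixels are derived on load, so augmented images are pure functions of the
  base image.
* Everything is reproducible from (spec, seed); renders are bit-identical
  per seed.

**What passing tests on this generator establish — and what they do not.**
They establish that the pipeline machinery is correct end-to-end: the
segmentation recovers a known region under six illuminations, the features
respond to pallor in the designed direction, and the classifier recovers the
known labels from those features (held-out macro F1 ≥ 0.9 at study scale;
in practice ≈ 1.0, since three well-separated Gaussian color classes are a
far easier problem than real tissue). They establish nothing about clinical
accuracy: real conjunctivas vary in vascular texture, specular highlights,
eyelashes, framing and camera response, none of which the generator renders.
Published headline accuracies from clinical studies of this design (~98–99 %
with AUC > 0.99 on ~600 images from 54 subjects) are not reproducible here
and are not targets of this package's tests.

## Geospatial aggregation

Screening records carry optional latitude/longitude. Cells are equal-degree
squares anchored at (−90, −180), half-open `[min, min + size)`, with the
north pole and antimeridian clamped into the last cell so every valid record
maps to exactly one cell. A cell is flagged when it holds ≥ `min_n` records
and its anemic fraction ≥ `threshold`; the moderate class counts as
non-anemic by default (clinical conservatism; configurable). Equal-degree
cells are not equal-area — adequate at screening scale, a known limitation
for high-latitude use. Output is CSV or GeoJSON; no cloud services are
involved.

## Problem sizes used in the test suite

Unit tests run on fixtures of at most a few hundred pixels or samples; the
end-to-end suite and `scripts/acceptance.py` use the full default study
scale (611 images at 256×256), which completes in about two minutes on one
CPU. Brute-force oracles (per-pixel feature loops, exhaustive
nearest-centroid checks, exhaustive-threshold ROC sweeps) are confined to
inputs small enough that their correctness is self-evident.

## Known limitations

* The baseline ROI detector assumes the conjunctiva is the largest reddish
  component in frame; it is a stand-in for a trained detector.
* k = 3 presumes three chromatic materials; occlusions, make-up or severe
  color casts violate this.
* Resubstitution numbers are reported for comparability but are optimistic.
* The synthetic generator does not model vascular texture, specularities or
  subject-level correlation: each record is an independent synthetic
  subject, whereas a real study images both eyes of each participant
  repeatedly and should be evaluated with subject-level splits.
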