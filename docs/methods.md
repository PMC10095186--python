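# Methods

## The measurement model

An imaging flow cytometer records, per event, a brightfield image and
fluorescence images for each stain, plus integrated channel
intensities. For dual RSG/PI staining of bacteria, the physiological
state maps onto the RSG × PI intensity plane as four clusters: active
(RSG⁺ PI⁻), dead (RSG⁻ PI⁺), and two double-positive mid-active groups
that differ in metabolic activity (mid-active II > mid-active I on
RSG). Raw acquisitions additionally contain non-cellular debris,
multi-cell aggregates and out-of-focus frames; quantifying
subpopulation percentages therefore requires image-based cleanup
before quadrant assignment.

The pipeline models this as a labelled mixture: each event carries a
ground-truth class, class-conditional bivariate log-normal RSG/PI
intensities, and class-conditional morphology/texture features. The
gating chain is then evaluated against the known labels.

## Synthetic-data generator

### Fluorescence geometry

Class centers and spreads (log10 RFU), chosen once to reproduce the
qualitative four-quadrant geometry of published RSG × PI dot plots (no
numeric gate positions or distribution parameters are published, so
these are documented calibration choices, configurable per run):

| class | μ(log RSG) | μ(log PI) | σ(RSG) | σ(PI) | ρ |
|---|---|---|---|---|---|
| active | 3.2 | 0.7 | 0.20 | 0.18 | 0.2 |
| mid-active I | 1.9 | 2.4 | 0.18 | 0.20 | 0.2 |
| mid-active II | 3.2 | 2.4 | 0.20 | 0.20 | 0.2 |
| dead | 0.7 | 3.2 | 0.18 | 0.25 | 0.2 |
| debris | 0.35 | 0.35 | 0.30 | 0.30 | 0.05 |

Adjacent class centers are separated by ≥ 1.2 decades (≥ 6 combined
SDs), so quadrant misassignment contributes ≪ 0.1 percentage points —
the synthetic populations are deliberately as well-separated as the
published dot plots show, not noisier.

### Composition presets

The published per-sample subpopulation percentages (3 strains × 6
treatments) are stored in `ifcgate.presets.COMPOSITIONS` and used as
generator inputs. They never sum to 100%; the remainder is exactly the
event mass the real gating chain removed, and is allocated 70% debris,
15% aggregates, 15% out-of-focus by default (`remainder_split`). This
allocation is a modelling choice; recovered percentages are insensitive
to it because all three nuisance classes are gated out upstream of the
quadrants.

### Nuisance events

* **Aggregates**: 2 + Poisson(0.8) member cells drawn from the sample's
  cell-class mixture; intensities are member sums, area is 0.9 × the
  summed member areas (overlap), aspect ratio uniform(0.25, 0.70).
  Stressed samples can be emulated by raising `f_aggregate`.
* **Debris**: log-normal area (median 0.4 µm², 0.35 dex) deliberately
  overlapping the single-cell area range, so a fraction of debris
  survives the shape gate and must be removed by the classifier — this
  is what motivates the machine-learning stage.
* **Out-of-focus events**: underlying cell-class intensities with a low
  Gradient RMS mode (N(12, 4) vs N(55, 7) in focus) and blur-inflated
  area.

Cell texture features (GLCM entropy/homogeneity statistics, major-axis
intensity) are drawn from class-conditional normals separated by ~3 SD
per feature between cells and debris, giving the 7-feature discriminant
a large combined separation, consistent with the near-clean
histogram separation shown for the published classifier.

### Image rendering

`render_event_image` draws a digitized ellipse (or touching-ellipse
chain for aggregates, random blob union for debris) at 0.05 µm/px into
a 96 px frame: brightfield is a dark silhouette on a bright noisy
background; each stain channel deposits the record's integrated
intensity inside the mask with gamma-distributed granularity, so the
extracted background-subtracted channel intensity is linear in the
generated intensity (verified to ~2%). Defocus is a Gaussian blur — no
optical point-spread-function physics is attempted. Rendering is used
to validate the feature extractors; the large-n pipeline runs operate
on generated feature tables directly.

### What the generator does *not* emulate

Spectral spillover/compensation, instrument drift, doublet images that
share one frame, saturation, autofluorescence, and strain-specific
morphology differences. Passing recovery tests therefore demonstrate
that the gating logic and calibration are correct under the stated
statistical model, not that the thresholds transfer to any particular
instrument; on real data every threshold is user-configurable.

## Feature definitions

* **Gradient RMS** — RMS of the central-difference gradient magnitude
  over mask pixels, divided by mean masked intensity (scale-invariant;
  0 for a constant image).
* **Shape** — area = pixel count × pixel size²; axes = 4·√(eigenvalues
  of the second-order central moments of the mask); aspect ratio =
  minor/major ∈ (0, 1], 1 = round. Matches the common moment-ellipse
  convention used by image-analysis toolkits.
* **Haralick statistics** — masked intensities quantized to 32
  equal-width levels (within-mask min–max); symmetric co-occurrence
  matrices at offset *g* for the four directions (0°, 45°, 90°, 135°),
  counting only pairs with both pixels in the mask; entropy
  −Σ p log₂ p and homogeneity Σ p/(1+|i−j|) per direction; reported as
  mean and (population) SD across directions. The trailing integers in
  instrument feature names (e.g. "…_9", "…_11") are interpreted as this
  offset. Diagonal offsets are exactly (±g, g) — not the rounded
  polar-coordinate offsets some libraries use — which is why the
  matrices are accumulated directly rather than via
  `skimage.feature.graycomatrix` (also: mask support and the |i−j|
  homogeneity kernel).
* **Major axis intensity** — major axis of the intensity-weighted
  second-moment ellipse, in µm.
* **Channel intensity** — sum over the mask of (pixel − median of
  unmasked pixels); invariant to additive offsets.

Undefined features (empty mask, offset larger than the object, zero
intensity mass) return NaN; gating routes such events to
`unclassified` instead of failing the batch.

## Classifier

Fisher linear discriminant on z-scored features (pooled training
mean/SD), ridge-regularized when the within-class scatter is singular.
Feature selection keeps the *k* = 7 largest |standardized weight|
candidates and refits — deterministic, unlike stepwise search. The
offset places the midpoint of the standardized class means at score 0;
orientation metadata records which class is positive (the published
table's uniformly negative weights correspond to the opposite
orientation, so orientation is explicit rather than implied by sign).
Training uses ~32 events per truth class, matching the protocol of
manually tagging 31–32 exemplar events. Numeric equality with the
published weights is not testable (standardization constants and
training data unpublished); the structural contract — 7 weighted
features, zero threshold — is.

## Gating and calibration

Order: focus → singles → classifier → quadrants; each event receives
exactly one terminal label. Quadrant rule on raw intensities: PI ≤ t_pi
and RSG > t_rsg ⇒ active; PI > t_pi split on RSG at t_rsg (dead below)
and t_mid (mid-active I between, mid-active II above); double-negative
⇒ unclassified.

Thresholds are calibrated on a *balanced reference mixture* (equal
fractions of the four subpopulations, 12% debris, 4% aggregates, 4%
defocus, same distributions), not on the analysed sample: gates in
practice are set on stained controls and applied across tubes, and a
balanced sample guarantees every histogram mode is populated regardless
of the experimental composition (a coated sample has < 1% active
events — no valley could be located reliably from it). Calibration
steps:

* focus: Otsu threshold on the reference Gradient RMS histogram;
* singles: 0.1st/99.9th percentiles of the reference single-cell area,
  0.1st percentile of aspect ratio (loses ~0.3% of true cells — the
  dominant, small, systematic bias of recovered percentages);
* quadrants: 100-bin histograms of log10 intensity, Gaussian-smoothed
  (σ = 2.5 bins); modes = peaks with ≥ 2% relative prominence taken in
  order of position; thresholds = the minima between consecutive modes
  (t_pi from the pooled PI histogram's first two modes; t_rsg and t_mid
  from the three RSG modes of PI-positive events). Intensities are
  floored at 10⁻³ RFU before the log.

The percentage denominator defaults to *all acquired events* because
the published per-sample percentages do not sum to 100 (consistent with
gated-out events remaining in the denominator); `gated_cells` is
available for sensitivity analysis.

## Enumeration, plating and sorting

* obj/mL = label count / acquired volume; the acquired volume is
  explicit user input (instruments report it per acquisition; it is not
  derivable from an event table).
* Plate counts: Poisson colonies at mean conc × 10^exponent × volume;
  an optional plating-efficiency factor < 1 emulates the systematic
  undercounting of culture-based methods. The estimator averages
  count/(10^exponent·volume) over plates with 30–300 colonies. Note a
  small (≈ +3%) selection bias at a 2.7 × 10⁸ cfu/mL ground truth: the
  10⁻⁷ plate (mean 27 colonies) qualifies only when it fluctuates to
  ≥ 30. This is a faithful property of the 30–300 convention, within
  the 5% recovery tolerance; `weighting="count_weighted"` (the Poisson
  maximum-likelihood combination) reduces it.
* Sorting: each of 24 single cells per subpopulation × medium grows
  with its class probability; growing wells follow
  OD(t) = od_max/(1+e^(−r(t−t_mid))) with t_mid ~ N(48 h, 10 h)
  truncated at 8 h and r = 0.3 h⁻¹, so most wells cross the OD600 = 0.1
  threshold (after blank subtraction) before the 48 h read and slow
  wells only by 72 h — growth counts are non-decreasing in time by
  construction. Growth percentages are reported as round(100·k/24, 1),
  reproducing the published percentage grid exactly. No fitting to
  real OD curves is attempted.

## Problem sizes and determinism

Recovery runs use 20,000 events (50,000 for the rare sub-1% active
composition) plus a 20,000-event calibration reference; at these sizes
binomial sampling error is ~0.3 points for mid-range fractions and a
full run takes well under a minute on one CPU. All generators consume
a `numpy.random.default_rng` seed and are bit-reproducible;
`recover_composition` derives its internal seeds (truth sets,
reference, sample) from the single seed argument.

## Known limitations

* FCS support is a minimal float32 list-mode FCS 3.0 reader/writer for
  interoperability, not a general FCS parser; proprietary instrument
  containers (.rif/.cif/.daf) are out of scope.
* Valley calibration assumes the reference histograms are multimodal
  with populated modes; it raises rather than guessing when modes are
  missing.
* The mid-active I/II split is a single RSG threshold among
  PI-positive events; more elaborate 2-D gate shapes are not modelled.
* Percentages reported for real samples depend on the denominator
  convention (see above); both conventions are computed, neither is
  "correct" in itself.
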