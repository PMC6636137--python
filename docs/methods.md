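# Methods

This note documents the models behind `mosqsub`: what the simulator
emulates, how the estimators and the bootstrap are defined, the numerical
conventions, and what a green test does and does not establish.

## The estimation problem

A trap catch of N specimens from S species is spread over a sorting sheet
of 25 grid cells. An analyst sorts only part of it and extrapolates three
quantities: the total N, the count/share of the single most abundant
species, and the species richness S. The package evaluates five ways of
doing that under a controlled, fully known ground truth.

## Synthetic samples

### Species composition

`generate_composition(n_species, total, dominance, seed)` gives the
dominant species `round(dominance × total)` specimens (clamped so every
other species keeps ≥ 1). The remainder follows a geometric rank-abundance
series with ratio 0.5, log-normally jittered (SD 0.3) per species, floored
at one specimen, with largest-remainder rounding — a one-knob model of the
strongly skewed compositions typical of flood-plain trap catches. Ties for
the most abundant species are broken by lexicographic label, so every
sample has exactly one well-defined dominant species.

Defaults of the study-level generator (`ExperimentConfig`): 23 samples;
totals log-uniform over [397, 4713] (the published range; the shape of the
distribution is unpublished, and a log-uniform reproduces the observed
right skew with mean ≈ 1500); species counts a rounded normal 8 ± 1.4
clipped to [2, 13]; dominance drawn per sample from U(0.35, 0.9), because
real catches differ in how strongly one taxon dominates and a constant
share would give the dominant-species proportion zero between-sample
variance (making its estimation correlation meaningless).

### Spatial allocation

Cell weights are one draw from a symmetric Dirichlet with concentration
θ per cell; all species are then allocated multinomially given the same
weights (clustering is physical — specimens pile up where they are poured
— not taxonomic). Cell totals are therefore Dirichlet-multinomial with
variance N·p(1−p)·(N+α₀)/(1+α₀), α₀ = 25θ, which the tests check against
simulation. θ → ∞ recovers the uniform multinomial. The field
overdispersion was never measured; **θ defaults to 5 as a documented
calibration knob, not a measured value**. An optional `edge_bias`
(default 0.8) down-weights the 16 peripheral cells, emulating the reported
tendency of specimens to end up away from the sheet edge. Specimens are
placed uniformly inside their cell.

### Biometrics

Per-specimen fresh mass and settled volume are lognormal with
species-level mean/CV (defaults 2.0 mg and 8 µl, CV 0.35 — the order of
magnitude of a blood-unfed adult *Aedes/Culex*). Per tube (cell):

* fresh weight = specimen-mass sum, rounded to the balance precision
  (default 0.1 mg, the practical precision of tube-difference weighing);
* dry weight = fresh × (1 − f), with f drawn per tube from
  Normal(0.273, 0.178) truncated to [0, 0.95] — the published drying
  statistics used as simulator truth;
* volume = specimen-volume sum rounded **up** to the tube graduation
  (meniscus-style scale read): 100 µl for 2 ml tubes, 500 µl for 15 ml
  tubes, selected by whether the raw volume exceeds 2 ml (the capacity
  threshold is a guess; the tube-type rule was only qualitative).

Truncation guarantees dry ≤ wet in every tube. In the noise-free limit
(CVs, SDs, precisions, graduations → 0) all measures are exactly
proportional to counts.

### Sheet photos

Specimens render as dark filled ellipses (3.2 × 1.4 mm mean, lognormal
size jitter, random orientation) on a light background (intensities
45/235) with additive Gaussian noise, at 2 px/mm. Replicate photos > 1
redraw all positions (the physical rearrangement between shots) with the
same true count. `allow_overlap=False` re-places blobs by rejection
sampling so components are provably disjoint — the fixture for exactness
tests. Not modelled: morphology, colour, lighting gradients, lens
distortion; image-based results on synthetic renders therefore say nothing
about a specific camera setup, only about the counting algorithm.

## Estimators

* area: est = (subsample count / k) × 25.
* volume/weight: est = subsample count × total measure / subsample
  measure. An empty subsample has no measurable fraction; inside the
  bootstrap its estimate is defined as 0 and the replicate is kept
  (discarding would bias small-k curves); the direct API raises instead.
* Species detection and the dominant-species proportion depend only on
  which cells were picked, so they are identical across the cell-based
  methods by construction. The most abundant species is identified on the
  full sample, never per subsample.
* fixed-n: SRSWOR is the reference mode; nearest-point mode assigns each
  random point its nearest still-available specimen in point order (ties:
  lowest specimen id) and exists to study spatial-selection bias.
* adjacent blocks: whole rows from the top of the sheet ({1..5} for 20 %,
  etc.) — the published block layouts are unavailable, so any fixed
  edge-connected convention is equally defensible; results depend only
  mildly on the shape.

A structural note: with noise-free measures the volume/weight estimator is
*exact* for every subset (the measured fraction equals the count
fraction), while the area estimator retains cell-sampling error. The
three curves coincide exactly only on equal-count-per-cell grids; with
realistic biometric noise they approach each other, and species-richness
curves are always identical. The biometric CVs are per-specimen and
average out over hundreds of specimens per tube, so the simulated
volume/weight curves are tighter than the area curve; field measures
carry additional per-tube error (packing, debris, moisture) that is not
modelled.

## Bootstrap evaluation

For each sample and k ∈ 1..25: B = 1000 uniform k-subsets (without
replacement within a draw; independent across draws), consistency
C = 100·est/actual per draw for totals, dominant-species count and
detected species; per (sample, k) the mean and the 2.5/97.5 percentile CI
(linear interpolation); then an equal-weight average across samples. The
error rate is mean |C − 100| (the study's "error rate" was never defined;
the CI half-width is reported alongside as the alternative reading).
Subsets depend only on (seed, sample, k) — never on the method — so
same-seed curves are comparable draw by draw. All randomness flows from
one root seed through named `SeedSequence` spawn streams; end-to-end runs
are byte-reproducible and the manifest records per-stage seeds and
checksums.

## Image calibration

THRESHOLD t ∈ 1..100 maps linearly to an 8-bit cutoff; foreground is
*strictly below* the cutoff, so pure paper white is never foreground even
at t = 100 (`binarize` is the single place to change the convention).
Components are 8-connected (4-connectivity via argument); SIZE is a pixel
area. The calibration evaluates all 10 000 pairs — one labelling pass per
threshold, with counts for all sizes derived from the sorted component
areas, which is exactly equivalent to the brute-force scan — and keeps
the full grid for audit. Best pair: mean consistency in [97.5, 102.5]
with minimal SD across images (ddof = 1); ties broken by |mean − 100|,
then smaller threshold, then smaller size; absent if no pair is in
window. Touching specimens merge and undercount by design.

## What green tests establish

The tests validate the machinery (identities, enumeration equivalence,
closed-form sampling theory, parameter recovery, exactness on separable
images) on a *simulated* world whose clustering strength, biometric CVs
and rendering are stated choices. They do not certify the field error
rates of any specific monitoring programme; those depend on the real
spatial clustering, size heterogeneity and photography, for which the
original per-cell data were never published.

## Known limitations

* θ and the biometric CVs are calibration knobs, not field measurements.
* The adjacent-block layouts are a convention.
* The image model cannot reproduce camera-specific optima; published
  THRESHOLD/SIZE values are tied to a physical setup and are not
  comparable to synthetic ones.
* Weight/volume per-tube measurement error beyond quantization and
  balance precision is not modelled, which flatters the measure-based
  estimators relative to field conditions.
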