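# Methods

## Scope and data model

The package analyses visible/near-infrared hyperspectral reflectance cubes
(rows × cols × bands with a strictly increasing wavelength grid in nm) of
meat-roll samples from three species — mutton, pork, duck — in raw or
cooked state. Reflectance is held internally as a fraction in [0, 1];
percentages appear only in reports, so the 0.15 segmentation threshold and
Eq-style calibration live on one consistent scale. Extracted sample spectra
travel in a `SpectrumTable` (samples × wavelengths plus species, state and
calibration/prediction assignment), serialized as plain CSV.

## Synthetic scenes

No measured cubes are distributed with the package, so `synthcube`
generates them. A species endmember is a monotone-by-segment cubic
(PCHIP) baseline through a handful of knots minus Gaussian dips
(center, σ, depth) at the absorption features of meat tissue: 415 nm
(Soret), 539/574 nm (deoxy-/oxymyoglobin), 637 nm (metmyoglobin, rendered
2.5× deeper when cooked), 761/980 nm (water O–H overtones) and 875 nm
(C–H fat). The baseline follows the characteristic shape: a low visible
plateau to ~650 nm, a high NIR plateau 650–850 nm, and a descent toward
1000 nm. Cooked endmembers add a constant +0.08 brightness offset.
Class separation is carried by the pigment-dip depths and the plateau
level; pork is brightest with the weakest pigment dips (the most distinct
class), duck darkest with the strongest.

Defaults are the study conditions: 300 evenly spaced channels over
380.6–1012.2 nm (≈2.11 nm spacing; the stated endpoints and channel count
fix the grid), 60 samples per species with the first 40 in calibration and
20 in prediction (180/120/60 in total), 64×64-pixel scenes with a 24-px
roll radius. A sample's spectra are the endmember times a per-sample
brightness factor ~ N(1, 0.03) (`within_class_sd`; biological and
preparation variability) plus additive per-pixel noise N(0, 0.005)
(`pixel_noise_sd`; sensor noise). Table rows are mean spectra, so their
residual noise is scaled by √(roll pixel count), exactly as extraction from
a cube would give. The background is spectrally flat at 0.08, which keeps
its 800−415 nm band difference near zero — segmentation separability is a
structural property of the scene, not a tuning. All draws come from
seed-sequence RNGs: identical (config, sample seed) pairs give
bit-identical cubes.

What the generator does **not** emulate: fat/lean spatial texture inside a
roll, cooking kinetics, specular highlights, wavelength-dependent sensor
noise, or inter-sample background variation. Passing tests therefore show
the pipeline is correct and recovers known structure under realistic noise;
they do not certify accuracy on real meat images.

## Calibration, segmentation, preprocessing

Calibration is per pixel and band: R = (I − D)/(W − D). Where
|W − D| < 10⁻⁶ of the intensity scale the ratio is undefined; such values
are clamped into [0, 1] and counted in a log record. Wavelength-to-band
lookup is always nearest-neighbour on the grid.

Segmentation subtracts the 415 nm band image from the 800 nm one and
thresholds at 0.15 (inclusive ≥, so boundary pixels are deterministic); no
morphological cleanup is applied. An empty ROI raises rather than returning
a silent zero spectrum. The two low-signal spectral edges are trimmed to
400–1000 nm before analysis (284 bands on the default grid).

Preprocessing transforms are pure and fit-free: SNV (sample sd, ddof 1),
min-max to [0, 1], unit-length scaling (a normalization variant), and
Savitzky–Golay 1st/2nd derivatives from a 5-point quadratic window scaled
by the band spacing in nm. Edge rule: the two bands at each end copy the
nearest interior value, keeping table width constant across methods. The
derivative spacing scale is a presentation choice (physical units per nm);
it is harmless to classifiers since it multiplies every band equally.

## PCA exploration

PCA is mean-centred only (bands share units). The loading-extremum picker
is a deterministic reading of "peaks and valleys with high absolute
coefficients": strict local extrema of |loading| above the 80th percentile,
pooled over the requested components, deduplicated within ±1 band, top-n by
magnitude.

## Wavelength selection

All three selectors optimise one shared criterion so their subsets are
comparable: the venetian-blinds cross-validated misclassification of a
PLS-DA restricted to the candidate bands. The criterion uses a fixed latent
variable count min(n_bands, n_classes) rather than an inner LV search —
deterministic, cheap, and adequate for subsets of ≤ 10 bands. Scores are
cached per subset (frozen-set key), which makes the stochastic searches
revisit states at no cost.

* **SPA** — for every start band, the projection chain takes at each step
  the column of largest norm orthogonal to the span of the chain so far
  (ties toward the lower index; collinear zero-norm columns skipped). Every
  prefix of length 1..10 of every chain is scored; the minimiser wins, ties
  to fewer bands then lower indices. Fully deterministic.
* **Random frog** — 1000-iteration subset chain: candidate size drawn
  ~ round(N(Q, 0.3 Q)) (clamped to [1, n_bands]); shrink drops random
  members, grow adds random non-members, equal size swaps one member. A
  better candidate always replaces the current subset; a worse one with
  probability 0.1 × (current error / candidate error). The output is the
  per-band inclusion frequency; the subset is the bands with frequency
  ≥ 0.25, capped at the top 8 by frequency, falling back to the top-Q₀
  bands if none clears the cutoff (so downstream modelling always has
  bands). Q₀ = 2, θ = 0.3, η = 0.1 follow the original random-frog
  formulation; only the iteration count is externally specified.
* **Simulated annealing** — states are subsets; moves swap one member for a
  non-member, plus grow/shrink when the size is free (bounded to [1, 10] to
  parallel SPA's range). ΔE ≤ 0 is always accepted, otherwise accepted with
  exp(−ΔE/T); T starts at 50 and is multiplied by 0.96 after each block of
  20 moves until it falls below 0.01 (~209 temperature levels). The
  best-ever state is returned. With the criterion bounded by 1, the early
  high-temperature phase is effectively a random walk; the final ~80 levels
  do the optimisation, and best-ever tracking makes the early phase
  harmless.

The reduction statistic is 100 × (n_full − n_selected)/n_full, reported to
one decimal.

## Classifiers

**PLS-DA**: NIPALS PLS2 on mean-centred X against centred one-hot class
indicators (a single ordinal label would impose a spurious class order;
the codebook preserves first-appearance order, mutton/pork/duck). The
number of latent variables (1..10) is chosen by venetian-blinds CV on the
calibration rows — class-stratified ordering, row i to fold i mod 10 — and
ties go to the smaller model; one NIPALS run per fold yields all LV counts.
Decoding is argmax over indicator scores; the continuous scores feed the
ROC. NIPALS stops early if a score collapses (rank exhausted).

**RBF-SVM**: calibration spectra are autoscaled (mean/sd of the calibration
set); c = 2^i and g = 2^j are grid-searched over integer exponents −8..8
(289 pairs) by the same CV scheme, ties to the smaller c then g exponent;
multi-class by one-vs-one voting (scikit-learn's SVC provides the QP
solver; decision scores are reordered to the codebook for ROC use).

Fitting functions operate on the calibration rows of the table they
receive and never inspect prediction rows (verified by a corruption test).

## Metrics

CCR = 100 × trace/total of the confusion matrix (rows true, columns
predicted). Per class one-vs-rest: SEN = TP/(TP+FN), SPE = TN/(TN+FP),
EFF = √(SEN·SPE). Kappa uses the standard multi-class expected agreement
Pe = Σᵢ rowᵢ·colᵢ/total². AUC is one-vs-rest per class (Mann–Whitney, ties
half) plus an unweighted macro mean; a single summary value per model is
deliberately not printed, since the class it would refer to is ambiguous —
all per-class values are reported. Undefined metrics (empty stratum,
absent class, Pe = 1) yield NaN with a warning instead of raising.
Reporting precision: CCR one decimal, ratio metrics two decimals.

## Classification maps

Foreground pixels (by the same band-math mask) are unfolded to a
pixels × bands matrix, given the model's preprocessing tag, restricted to
the model's bands (compatibility checked against the wavelengths recorded
on the model), predicted, and folded back. No spatial smoothing or majority
filtering is applied, so maps keep their per-pixel speckle; the modal
foreground class is the map-level species call. Palette: mutton green,
pork yellow, duck red, background black; PNG export is lossless.

## Problem sizes in tests and the acceptance script

The stochastic-selector suites run 20 seeds each on compact tables
(60 samples × 40 bands with two informative bands; the frequency test uses
two classes × 8 samples × 10 bands), large enough to separate signal from
noise bands yet quick to cross-validate. The enumerable annealing check
uses 8 bands with fixed subset size 2 (28 states). The end-to-end suites
use the full default dataset (180 × 284 after trimming) and render 10–20
scenes per species for the map checks. These sizes are the package's
choices for routine verification; all generator noise parameters stay at
their defaults throughout.

## Known limitations

* The ENVI reader covers the plain header + BSQ/BIL/BIP binary layout with
  the common numeric types; vendor-specific raw formats are out of scope.
* The random-frog acceptance-probability form (η-scaled error ratio) is one
  reasonable member of the family of ratio rules; selection frequencies are
  stable across seeds but not canonical.
* PLS-DA assumes classes are linearly separable in latent-variable space
  after centring; strongly nonlinear class structure is the SVM's job.
* Synthetic realism is deliberately limited (see above); absolute metric
  values on real instruments will differ even though the pipeline
  mechanics are identical.
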