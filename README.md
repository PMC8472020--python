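# hsimeat

Hyperspectral-imaging (HSI) chemometrics for meat-species authentication.

Meat rolls — thin slices of frozen meat widely used in hot-pot cooking — are
a common target of species substitution: cheaper pork or duck passed off as
mutton, raw or cooked. Visible/near-infrared HSI (here 300 channels over
380.6–1012.2 nm) records a full reflectance spectrum at every image pixel,
so species-specific absorption features (the Soret haemoglobin band at
415 nm, deoxy-/oxymyoglobin at 539/574 nm, metmyoglobin near 637 nm, water
O–H overtones at 761/980 nm, a C–H fat band near 875 nm) can be read out
non-destructively and mapped spatially.

The package implements the full analysis chain used for this problem:

1. **Calibration** — reflectance R = (I − D)/(W − D) against white (~99.9%)
   and dark references, per pixel and band (ENVI cube I/O included).
2. **Segmentation** — band math (image at 800 nm minus image at 415 nm) and
   a fixed 0.15 threshold isolate the roll; the ROI mean spectrum is the
   sample's observation.
3. **Preprocessing** — SNV, min-max normalization, Savitzky–Golay 1st/2nd
   derivatives (5-point quadratic window); all fit-free, per spectrum.
4. **Exploration** — mean-centred PCA score/loading plots and a
   deterministic loading-extremum wavelength picker.
5. **Wavelength selection** — successive projections algorithm (SPA, chain
   lengths N = 1..10), random frog (1000-iteration subset chain with
   per-band selection frequencies), and simulated annealing (initial
   temperature 50, cooling rate 0.96), all scored by the same
   venetian-blinds cross-validated PLS-DA misclassification.
6. **Classification** — PLS-DA (NIPALS on one-hot class indicators, latent
   variables chosen by venetian-blinds CV, argmax decoding) and RBF-SVM
   (grid search over c = 2^i, g = 2^j, integer i, j in [−8, 8]).
7. **Evaluation** — CCR, per-class one-vs-rest SEN/SPE and their geometric
   mean EFF = √(SEN·SPE), Cohen's kappa, and one-vs-rest ROC/AUC.
8. **Mapping** — pixel-wise classification maps (mutton green, pork yellow,
   duck red, background black) with per-class pixel percentages.

The measured cubes of the original experiment are not publicly deposited,
so a first-class synthetic generator (`hsimeat.synthcube`) emulates the
study conditions — species endmembers with the absorption features above,
circular rolls on a dark background, per-sample brightness variation and
pixel noise, 60 samples per species split 40/20 into calibration and
prediction — and supplies ground truth for every downstream check.

## Worked example

```python
import hsimeat as h
from hsimeat import wavesel

config = h.SynthConfig(seed=0)                       # the study conditions
table  = h.make_dataset(config, h.default_profiles("raw").values())
table  = h.trim_spectral(table, 400, 1000)           # drop low-SNR edges

subset  = h.spa_select(table, wavesel.SPAConfig(1, 10))
reduced = table.select_bands(subset.band_indices)
model   = h.plsda_fit(reduced, max_lvs=10, cv=h.CVScheme(n_splits=10))

labels, scores = h.plsda_predict(model, reduced.prediction().spectra)
```

Printed by `examples/03_wavelength_selection.py` and
`examples/04_classify_and_evaluate.py` on these defaults:

```
spa: 2 bands [653.1, 931.9] (CV misclassification 0.000, reduction 99.3%)
 rf: 2 bands [634.1, 942.5] (CV misclassification 0.025, reduction 99.3%)
saa: 3 bands [708.0, 782.0, 906.6] (CV misclassification 0.000, reduction 98.9%)

PLS-DA (3 latent variables):
prediction: CCR = 100.0%  kappa = 1.00  macro AUC = 1.00
  mutton: SEN = 1.00  SPE = 1.00  EFF = 1.00  AUC = 1.00
  pork: SEN = 1.00  SPE = 1.00  EFF = 1.00  AUC = 1.00
  duck: SEN = 1.00  SPE = 1.00  EFF = 1.00  AUC = 1.00
```

SPA keeps 2 of 284 bands (a 99.3% reduction) with no loss of accuracy: the
prediction-set CCR (percent of the 60 held-out samples assigned their true
species) stays at 100%, and all per-class sensitivities/specificities are
perfect at this class separation. `examples/05_classification_maps.py`
then renders pixel-wise maps whose modal class identifies each roll:

```
true mutton: modal class mutton, pixel percentages {'mutton': 82.43, 'pork': 0.0, 'duck': 17.57}
true   pork: modal class   pork, pixel percentages {'mutton': 5.71, 'pork': 94.29, 'duck': 0.0}
true   duck: modal class   duck, pixel percentages {'mutton': 5.32, 'pork': 0.0, 'duck': 94.68}
```

A thin CLI mirrors the library (`hsimeat simulate`, `calibrate`, `segment`,
`extract`, `all`, `map`); `hsimeat all` runs the whole pipeline from a YAML
config and writes the report, subsets and maps to an output directory.

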