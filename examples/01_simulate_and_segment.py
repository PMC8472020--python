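"""Render a synthetic meat-roll scene, calibrate it, and segment the roll.

Builds one pork-roll reflectance cube, converts it to raw sensor intensity,
calibrates it back with white/dark references, then isolates the roll with
the 800 nm - 415 nm band-math threshold.
"""

import numpy as np

import hsimeat as h
from hsimeat import segmentation, synthcube

config = h.SynthConfig(seed=42)
profile = h.default_profiles("raw")["pork"]

reflectance, truth = h.render_sample_cube(config, profile, sample_seed=0)
refs = h.make_reference_pair(config)
raw = synthcube.to_raw_intensity(reflectance, refs)

calibrated = h.calibrate(raw, refs)
diff = segmentation.band_difference(calibrated)  # 800 nm minus 415 nm
mask = segmentation.threshold_mask(diff, 0.15)
spectrum = h.extract_mean_spectrum(calibrated, mask)

print(f"cube: {calibrated.shape[0]}x{calibrated.shape[1]} pixels, "
      f"{calibrated.n_bands} bands "
      f"({calibrated.wavelengths[0]:.1f}-{calibrated.wavelengths[-1]:.1f} nm)")
print(f"foreground pixels: {mask.n_foreground} "
      f"(ground truth {int(truth.sum())})")
agreement = np.mean(mask.grid == truth)
print(f"mask agreement with ground truth: {100 * agreement:.2f}%")
i800 = calibrated.band_index(800)
i415 = calibrated.band_index(415)
print(f"mean ROI reflectance at 800 nm: {spectrum[i800]:.3f}, "
      f"at 415 nm: {spectrum[i415]:.3f}")
# The roll reflects strongly in the NIR and weakly at the Soret pigment
# band, so the band difference cleanly separates it from the flat background.
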