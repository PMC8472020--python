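"""Explore the class structure of the spectra with PCA.

Fits a two-component PCA to the calibration spectra of the default raw
dataset and picks discriminative wavelengths from the loading extrema.
"""

import numpy as np

import hsimeat as h

config = h.SynthConfig(seed=0)
table = h.make_dataset(config, h.default_profiles("raw").values())
table = h.trim_spectral(table, 400, 1000)

pca = h.pca_fit(table.calibration(), k=2)
print("explained variance: "
      + ", ".join(f"PC{i + 1} {f:.1%}" for i, f in
                  enumerate(pca.explained_fraction)))

subset = h.select_loading_wavelengths(pca, pcs=[1, 2], n_top=5)
print(f"loading-extremum wavelengths (nm): "
      f"{np.round(subset.wavelengths_nm, 1).tolist()}")
# The first two components carry almost all the spectral variance; the
# loading peaks/valleys mark the bands that drive the species separation
# (pigment dips in the visible, plateau level in the NIR).
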