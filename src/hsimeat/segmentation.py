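"""Band-math segmentation and mean-spectrum extraction.

The meat roll reflects far more near-infrared light (around 800 nm) than
violet light (the Soret pigment absorption near 415 nm), while the dark
background is spectrally flat. Subtracting the 415 nm band image from the
800 nm one and thresholding the difference at 0.15 (reflectance fraction)
therefore isolates the roll as the region of interest; the mean spectrum
over the retained pixels is the sample's observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .cube_io import SpectralCube
from .errors import DimensionError, EmptyROIError

DEFAULT_HIGH_NM = 800.0
DEFAULT_LOW_NM = 415.0
DEFAULT_THRESHOLD = 0.15


@dataclass
class Mask:
    """Boolean foreground mask with the same spatial shape as its cube."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise DimensionError("mask grid must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    def to_png(self, path) -> None:
        """Export as 8-bit PNG (foreground 255, background 0) for inspection."""
        Image.fromarray((self.grid * 255).astype(np.uint8), mode="L").save(path)


def band_difference(
    cube: SpectralCube, high_nm: float = DEFAULT_HIGH_NM, low_nm: float = DEFAULT_LOW_NM
) -> np.ndarray:
    """Band-math image: reflectance at ``high_nm`` minus at ``low_nm``."""
    return cube.band_image(high_nm) - cube.band_image(low_nm)


def threshold_mask(image: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> Mask:
    """Fixed-threshold foreground mask (inclusive: foreground where >= threshold)."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise DimensionError("threshold_mask requires a finite image")
    return Mask(image >= threshold)


def segment(cube: SpectralCube, threshold: float = DEFAULT_THRESHOLD, *,
            high_nm: float = DEFAULT_HIGH_NM, low_nm: float = DEFAULT_LOW_NM) -> Mask:
    """Full segmentation: band difference then fixed threshold."""
    return threshold_mask(band_difference(cube, high_nm, low_nm), threshold)


def extract_mean_spectrum(cube: SpectralCube, mask: Mask) -> np.ndarray:
    """Per-band arithmetic mean over the masked pixels."""
    if mask.grid.shape != cube.shape[:2]:
        raise DimensionError("mask shape does not match cube spatial shape")
    if mask.n_foreground == 0:
        raise EmptyROIError("empty mask: segmentation retained no pixels")
    return cube.data[mask.grid].mean(axis=0)
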