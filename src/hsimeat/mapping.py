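"""Pixel-wise classification maps.

Foreground pixels of a reflectance cube are unfolded to a pixels x bands
matrix, pushed through a fitted classifier on its selected bands, and the
predicted labels are folded back onto the image grid; the background stays
black. Pixel spectra receive the same preprocessing as the model's training
spectra before band selection, and no spatial smoothing is applied, so the
maps keep their natural per-pixel speckle. The per-class share of foreground
pixels summarises each map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .cube_io import SpectralCube
from .errors import CompatibilityError, EmptyROIError, LegendError
from .models import PLSDAModel, SVMModel, plsda_predict, svm_predict
from .preprocess import apply_preprocess_matrix
from .segmentation import Mask
from .wavesel import WavelengthSubset

BACKGROUND = "background"

DEFAULT_PALETTE = {
    "mutton": (0, 255, 0),  # green
    "pork": (255, 255, 0),  # yellow
    "duck": (255, 0, 0),  # red
    BACKGROUND: (0, 0, 0),  # black
}


@dataclass
class ClassMap:
    label_grid: np.ndarray  # 2-D array of label strings
    legend: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))

    @property
    def foreground(self) -> np.ndarray:
        return self.label_grid != BACKGROUND

    def modal_class(self) -> str:
        """Most frequent foreground label (the map-level species call)."""
        labels, counts = np.unique(self.label_grid[self.foreground],
                                   return_counts=True)
        return str(labels[np.argmax(counts)])


def classify_pixels(
    cube: SpectralCube,
    mask: Mask,
    model: PLSDAModel | SVMModel,
    subset: WavelengthSubset,
) -> ClassMap:
    """Predict a species for every foreground pixel of a cube.

    The model must have been trained on exactly the subset's bands (checked
    against the wavelengths recorded on the model).
    """
    if mask.grid.shape != cube.shape[:2]:
        raise CompatibilityError("mask shape does not match cube")
    if (
        model.wavelengths is None
        or model.wavelengths.shape != subset.wavelengths_nm.shape
        or not np.allclose(model.wavelengths, subset.wavelengths_nm)
    ):
        raise CompatibilityError(
            "model was not trained on the bands of this subset"
        )
    # subset indices refer to the cube's (trimmed) grid
    if subset.band_indices.size and not np.allclose(
        cube.wavelengths[subset.band_indices], subset.wavelengths_nm
    ):
        raise CompatibilityError("subset indices do not match the cube grid")
    grid = np.full(cube.shape[:2], BACKGROUND, dtype=object)
    if mask.n_foreground:
        pixels = cube.data[mask.grid]
        pixels = apply_preprocess_matrix(pixels, model.preprocess, cube.wavelengths)
        pixels = pixels[:, subset.band_indices]
        predict = plsda_predict if isinstance(model, PLSDAModel) else svm_predict
        labels, _ = predict(model, pixels)
        grid[mask.grid] = labels
    return ClassMap(label_grid=grid)


def pixel_percentages(cmap: ClassMap, classes=None) -> dict:
    """Percent of foreground pixels per class, two decimals."""
    fg = cmap.label_grid[cmap.foreground]
    if fg.size == 0:
        raise EmptyROIError("class map has no foreground pixels")
    if classes is None:
        classes = [c for c in cmap.legend if c != BACKGROUND]
    return {c: round(100.0 * float((fg == c).sum()) / fg.size, 2) for c in classes}


def colorize(cmap: ClassMap) -> np.ndarray:
    """Render the label grid to an RGB uint8 image via the legend."""
    rows, cols = cmap.label_grid.shape
    rgb = np.zeros((rows, cols, 3), dtype=np.uint8)
    for label in np.unique(cmap.label_grid):
        if label not in cmap.legend:
            raise LegendError(f"label {label!r} missing from legend")
        rgb[cmap.label_grid == label] = cmap.legend[label]
    return rgb


def save_map_png(cmap: ClassMap, path) -> None:
    Image.fromarray(colorize(cmap), mode="RGB").save(path)
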