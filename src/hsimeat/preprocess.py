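"""Per-spectrum preprocessing transforms.

All transforms are pure, fit-free (no training-set statistics) and
length-preserving, so they commute with the calibration/prediction split:

* ``snv`` — standard normal variate: centre to zero mean, scale to unit
  sample standard deviation (removes multiplicative scatter).
* ``minmax`` — rescale to span [0, 1].
* ``unit`` — scale to unit Euclidean length (offered as a normalization
  variant; min-max is the primary one).
* ``deriv1`` / ``deriv2`` — Savitzky-Golay derivatives: the derivative of a
  local least-squares quadratic over a five-point moving window, scaled by
  the actual band spacing in nm. The two bands at each end take the value
  of the nearest interior point so every method keeps the table width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DegenerateSpectrumError, DimensionError
from .table import SpectrumTable

METHODS = ("none", "snv", "minmax", "unit", "deriv1", "deriv2")


@dataclass
class PreprocessSpec:
    method: str = "none"
    sg_window: int = 5
    sg_polyorder: int = 2

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigError(f"unknown preprocessing method {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError("sg_window must be odd and > sg_polyorder")


def snv(spectrum: np.ndarray) -> np.ndarray:
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise DegenerateSpectrumError("SNV needs at least two bands")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError("SNV undefined for a constant spectrum")
    return (x - x.mean()) / sd


def minmax_normalize(spectrum: np.ndarray) -> np.ndarray:
    x = np.asarray(spectrum, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSpectrumError("min-max undefined for a constant spectrum")
    return (x - lo) / (hi - lo)


def unit_length(spectrum: np.ndarray) -> np.ndarray:
    x = np.asarray(spectrum, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise DegenerateSpectrumError("unit-length undefined for a zero spectrum")
    return x / norm


def sg_derivative(
    spectrum: np.ndarray,
    order: int,
    spec: PreprocessSpec | None = None,
    *,
    delta: float = 1.0,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Savitzky-Golay derivative of the stated order (1 or 2).

    ``delta`` is the band spacing used to express the derivative per nm;
    passing ``wavelengths`` derives it from the (uniform) grid.
    """
    if order not in (1, 2):
        raise ConfigError("derivative order must be 1 or 2")
    spec = spec or PreprocessSpec(method=f"deriv{order}")
    x = np.asarray(spectrum, dtype=float)
    if x.size < spec.sg_window:
        raise DimensionError(
            f"spectrum of length {x.size} shorter than window {spec.sg_window}"
        )
    if wavelengths is not None:
        delta = float(np.mean(np.diff(wavelengths)))
    y = savgol_filter(
        x, spec.sg_window, spec.sg_polyorder, deriv=order, delta=delta
    )
    hw = spec.sg_window // 2
    y[:hw] = y[hw]  # constant edge rule: copy nearest interior value
    y[-hw:] = y[-hw - 1]
    return y


def apply_preprocess(table: SpectrumTable, spec: PreprocessSpec) -> SpectrumTable:
    """Apply a transform row-wise to a spectrum table (returns a new table)."""
    if spec.method == "none":
        return table
    delta = float(np.mean(np.diff(table.wavelengths)))
    if spec.method == "snv":
        rows = [snv(r) for r in table.spectra]
    elif spec.method == "minmax":
        rows = [minmax_normalize(r) for r in table.spectra]
    elif spec.method == "unit":
        rows = [unit_length(r) for r in table.spectra]
    else:
        order = 1 if spec.method == "deriv1" else 2
        rows = [sg_derivative(r, order, spec, delta=delta) for r in table.spectra]
    out = table.rows(np.arange(len(table)))
    out.spectra = np.array(rows)
    return out


def apply_preprocess_matrix(X: np.ndarray, spec: PreprocessSpec, wavelengths) -> np.ndarray:
    """Same transform on a bare (n, bands) matrix (used for pixel spectra)."""
    if spec.method == "none":
        return np.asarray(X, dtype=float)
    delta = float(np.mean(np.diff(wavelengths)))
    if spec.method == "snv":
        return np.array([snv(r) for r in X])
    if spec.method == "minmax":
        return np.array([minmax_normalize(r) for r in X])
    if spec.method == "unit":
        return np.array([unit_length(r) for r in X])
    order = 1 if spec.method == "deriv1" else 2
    return np.array([sg_derivative(r, order, spec, delta=delta) for r in X])
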