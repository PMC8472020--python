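"""Hyperspectral cube data model, ENVI I/O, reflectance calibration and trimming.

A cube is a rows x cols x bands array with a strictly increasing wavelength
vector in nm. Raw sensor intensity cubes are converted to reflectance with
white/dark reference cubes:

    R = (I_raw - D) / (W - D)

where W is a near-perfect (~99.9%) white reference and D the dark current.
Reflectance is stored as a fraction in [0, 1]; percent appears only in
reports. ENVI files are the plain key = value header plus a flat binary
block in BSQ, BIL or BIP interleave.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    DimensionError,
    EmptySelectionError,
    FormatError,
    InvalidGridError,
)
from .table import SpectrumTable

logger = logging.getLogger(__name__)

RAW_INTENSITY = "raw_intensity"
REFLECTANCE = "reflectance"

# ENVI numeric codes for the dtypes we read/write
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """3-D spectral image: ``data[row, col, band]`` plus its wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = REFLECTANCE

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths.size:
            raise DimensionError(
                f"{self.data.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise InvalidGridError("wavelengths must be strictly increasing")
        if self.kind not in (RAW_INTENSITY, REFLECTANCE):
            raise FormatError(f"unknown cube kind {self.kind!r}")
        if self.kind == REFLECTANCE and not np.all(np.isfinite(self.data)):
            raise FormatError("reflectance cube contains non-finite values")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, nm: float) -> int:
        """Nearest-neighbour band lookup on the wavelength grid."""
        return nearest_band(self.wavelengths, nm)

    def band_image(self, nm: float) -> np.ndarray:
        return self.data[:, :, self.band_index(nm)]


@dataclass
class ReferencePair:
    """White (~100%) and dark (~0%) reference cubes on the sample grid."""

    white: SpectralCube
    dark: SpectralCube

    def __post_init__(self):
        if self.white.shape != self.dark.shape:
            raise DimensionError("white and dark reference shapes differ")
        if not np.array_equal(self.white.wavelengths, self.dark.wavelengths):
            raise DimensionError("white and dark wavelength grids differ")


def nearest_band(wavelengths: np.ndarray, nm: float, warn_spacing: bool = False) -> int:
    wavelengths = np.asarray(wavelengths, dtype=float)
    idx = int(np.argmin(np.abs(wavelengths - nm)))
    if warn_spacing and wavelengths.size > 1:
        spacing = float(np.median(np.diff(wavelengths)))
        if abs(wavelengths[idx] - nm) > spacing:
            warnings.warn(
                f"requested {nm} nm is outside the grid by more than one band "
                f"spacing; using nearest band at {wavelengths[idx]:.1f} nm",
                stacklevel=2,
            )
    return idx


# ---------------------------------------------------------------------------
# ENVI I/O


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing ENVI magic line")
    header: dict = {}
    body = text.lstrip()[4:]
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value:
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{} ")
            header[key] = [v.strip() for v in value.split(",") if v.strip()]
        else:
            header[key] = value
    return header


def read_envi(header_path, data_path=None) -> SpectralCube:
    """Read an ENVI header + binary data pair into a :class:`SpectralCube`."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    header = _parse_envi_header(header_path.read_text())
    try:
        samples = int(header["samples"])
        lines = int(header["lines"])
        bands = int(header["bands"])
        interleave = str(header["interleave"]).lower()
        dtype_code = int(header["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in header:
        raise FormatError("ENVI header missing wavelength list")
    wavelengths = np.array([float(w) for w in header["wavelength"]])
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    raw = np.fromfile(Path(data_path), dtype=_ENVI_DTYPES[dtype_code])
    if raw.size != samples * lines * bands:
        raise FormatError("data file size does not match header dimensions")
    if interleave == "bsq":  # (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    kind = header.get("cube kind", REFLECTANCE)
    return SpectralCube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_envi(cube: SpectralCube, header_path, data_path=None, interleave="bsq") -> None:
    """Write a cube as ENVI header + binary data; round-trips bit-exactly."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    data = np.asarray(cube.data, dtype=np.float64)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        block = data.transpose(2, 0, 1)
    elif interleave == "bil":
        block = data.transpose(0, 2, 1)
    else:
        block = data
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"cube kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(block).tofile(Path(data_path))


# ---------------------------------------------------------------------------
# Calibration and trimming


def calibrate(raw: SpectralCube, refs: ReferencePair, epsilon: float = 1e-6) -> SpectralCube:
    """Reflectance calibration R = (I - D) / (W - D), stored as a fraction.

    Pixels/bands where |W - D| < ``epsilon`` (on the intensity scale) are
    undefined; they are clamped into [0, 1] and counted in a log record.
    """
    if raw.shape != refs.white.shape:
        raise DimensionError(
            f"sample cube {raw.shape} does not match references {refs.white.shape}"
        )
    if not np.array_equal(raw.wavelengths, refs.white.wavelengths):
        raise DimensionError("sample and reference wavelength grids differ")
    denom = refs.white.data - refs.dark.data
    degenerate = np.abs(denom) < epsilon
    safe = np.where(degenerate, 1.0, denom)
    refl = (raw.data - refs.dark.data) / safe
    n_bad = int(degenerate.sum()) + int(((refl < 0) | (refl > 1)).sum())
    refl = np.clip(np.where(degenerate, 0.0, refl), 0.0, 1.0)
    if n_bad:
        logger.info("calibrate: clamped %d degenerate/out-of-range values", n_bad)
    return SpectralCube(refl, raw.wavelengths.copy(), kind=REFLECTANCE)


def trim_spectral(obj, low_nm: float, high_nm: float):
    """Keep only the bands with low <= lambda <= high (inclusive, order kept).

    Works on :class:`SpectralCube` and :class:`SpectrumTable` alike.
    """
    if low_nm > high_nm:
        raise InvalidGridError("trim range low > high")
    wl = obj.wavelengths
    keep = np.flatnonzero((wl >= low_nm) & (wl <= high_nm))
    if keep.size == 0:
        raise EmptySelectionError(
            f"no band in [{low_nm}, {high_nm}] nm on grid "
            f"[{wl[0]:.1f}, {wl[-1]:.1f}]"
        )
    if isinstance(obj, SpectralCube):
        return replace(obj, data=obj.data[:, :, keep], wavelengths=wl[keep])
    if isinstance(obj, SpectrumTable):
        return obj.select_bands(keep)
    raise TypeError(f"cannot trim object of type {type(obj).__name__}")


def pseudo_rgb(cube: SpectralCube, r_nm=640.0, g_nm=550.0, b_nm=460.0) -> np.ndarray:
    """False-colour image from the bands nearest three visible wavelengths.

    Each channel is min-max rescaled to [0, 1] over the whole frame
    (foreground plus background); a constant band maps to mid-grey.
    """
    channels = []
    for nm in (r_nm, g_nm, b_nm):
        idx = nearest_band(cube.wavelengths, nm, warn_spacing=True)
        band = cube.data[:, :, idx].astype(float)
        lo, hi = band.min(), band.max()
        channels.append((band - lo) / (hi - lo) if hi > lo else np.full_like(band, 0.5))
    return np.stack(channels, axis=-1)
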