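"""Seeded synthetic hyperspectral scenes of meat-roll samples.

The generator emulates the study conditions the analysis assumes: 300-channel
reflectance cubes spanning 380.6-1012.2 nm, three species classes (mutton,
pork, duck) in raw and cooked states, a circular meat-roll foreground on a
dark flat background, and a 40/20 per-class calibration/prediction split.

Each species endmember is a smooth baseline (monotone cubic interpolation
through a handful of knots) minus Gaussian absorption dips at the pigment,
water and fat bands seen in visible/NIR meat spectra: the Soret band near
415 nm, deoxy-/oxymyoglobin at 539/574 nm, metmyoglobin near 637 nm
(stronger when cooked), O-H water overtones at 761 and 980 nm and a weak
C-H fat band near 875 nm. Cooked endmembers add a constant brightness
offset (cooked rolls reflect more than raw). Class separation lives chiefly
in the pigment-dip depths and the NIR plateau level, with pork given the
most distinct plateau.

Every draw is made from a seed-sequence RNG, so cubes, samples and datasets
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .cube_io import RAW_INTENSITY, REFLECTANCE, ReferencePair, SpectralCube
from .errors import ConfigError, GeometryError, InvalidGridError
from .table import CAL, PRED, SpectrumTable

SPECIES = ("mutton", "pork", "duck")
BAND_RANGE_NM = (380.6, 1012.2)


@dataclass
class SpeciesProfile:
    """Pure-class reflectance endmember parameterization."""

    species: str
    state: str  # 'raw' | 'cooked'
    baseline_knots: tuple  # ((nm, reflectance fraction), ...)
    dips: tuple  # ((center nm, sigma nm, depth fraction), ...)
    brightness_offset: float = 0.08  # added in the cooked state

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ConfigError(f"unknown species {self.species!r}")
        if self.state not in ("raw", "cooked"):
            raise ConfigError(f"unknown state {self.state!r}")
        lo, hi = BAND_RANGE_NM
        for center, _sigma, _depth in self.dips:
            if not lo <= center <= hi:
                raise ConfigError(f"dip center {center} nm outside sensor range")


@dataclass
class SynthConfig:
    """Scene and dataset parameters (defaults are the study conditions)."""

    seed: int = 0
    image_shape: tuple = (64, 64)
    n_bands: int = 300
    band_range_nm: tuple = BAND_RANGE_NM
    n_per_class: int = 60
    cal_per_class: int = 40
    roll_radius_px: int = 24
    within_class_sd: float = 0.03  # sd of the per-sample brightness factor
    pixel_noise_sd: float = 0.005  # additive reflectance noise per pixel/band
    background_level: float = 0.08  # flat background reflectance

    def __post_init__(self):
        if self.cal_per_class >= self.n_per_class:
            raise ConfigError("cal_per_class must be < n_per_class")
        if self.pixel_noise_sd < 0 or self.within_class_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not 0 <= self.background_level < 0.15:
            # flat background => band-math difference ~0, but keep the level
            # itself well below the segmentation threshold too
            raise ConfigError("background_level must lie in [0, 0.15)")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.band_range_nm
        return np.linspace(lo, hi, self.n_bands)


def make_endmember(profile: SpeciesProfile, wavelengths: np.ndarray) -> np.ndarray:
    """Render a profile to a reflectance spectrum on the given grid."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise InvalidGridError("wavelength grid must be strictly increasing")
    lo, hi = BAND_RANGE_NM
    if wl[0] < lo - 1e-9 or wl[-1] > hi + 1e-9:
        raise InvalidGridError("wavelength grid outside the sensor range")
    knots = np.asarray(profile.baseline_knots, dtype=float)
    spectrum = PchipInterpolator(knots[:, 0], knots[:, 1])(wl)
    for center, sigma, depth in profile.dips:
        spectrum = spectrum - depth * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    if profile.state == "cooked":
        spectrum = spectrum + profile.brightness_offset
    return np.clip(spectrum, 0.0, 1.0)


def default_profiles(state: str = "raw") -> dict:
    """The three built-in species endmember profiles for one state.

    Depth/plateau choices encode the qualitative class structure: pork is
    brightest with the weakest pigment dips (most distinct), duck darkest
    with the strongest pigment dips, mutton in between.
    """

    def dips(d539, d574, d637, d875, d415=0.045, d761=0.030, d980=0.040):
        return (
            (415.0, 10.0, d415),
            (539.0, 8.0, d539),
            (574.0, 8.0, d574),
            (637.0, 8.0, d637 * (2.5 if state == "cooked" else 1.0)),
            (761.0, 10.0, d761),
            (875.0, 12.0, d875),
            (980.0, 14.0, d980),
        )

    knots = {
        "mutton": (
            (380.6, 0.105), (430.0, 0.115), (500.0, 0.125), (560.0, 0.135),
            (620.0, 0.21), (680.0, 0.47), (750.0, 0.55), (850.0, 0.56),
            (930.0, 0.50), (1012.2, 0.38),
        ),
        "pork": (
            (380.6, 0.145), (430.0, 0.16), (500.0, 0.175), (560.0, 0.185),
            (620.0, 0.27), (680.0, 0.55), (750.0, 0.63), (850.0, 0.64),
            (930.0, 0.57), (1012.2, 0.44),
        ),
        "duck": (
            (380.6, 0.085), (430.0, 0.09), (500.0, 0.10), (560.0, 0.11),
            (620.0, 0.18), (680.0, 0.41), (750.0, 0.48), (850.0, 0.49),
            (930.0, 0.43), (1012.2, 0.33),
        ),
    }
    depth = {
        "mutton": dips(0.035, 0.035, 0.008, 0.018),
        "pork": dips(0.018, 0.018, 0.004, 0.030),
        "duck": dips(0.050, 0.050, 0.012, 0.010),
    }
    return {
        sp: SpeciesProfile(sp, state, knots[sp], depth[sp]) for sp in SPECIES
    }


def _disk_mask(shape, radius):
    rows, cols = shape
    if 2 * radius >= min(rows, cols):
        raise GeometryError(
            f"roll radius {radius} px does not fit a {rows}x{cols} frame"
        )
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def render_sample_cube(
    config: SynthConfig, profile: SpeciesProfile, sample_seed: int
) -> tuple:
    """Render one meat-roll scene; returns (reflectance cube, truth mask).

    Foreground pixels are ``endmember * f + noise`` with a per-sample
    brightness factor ``f ~ N(1, within_class_sd)``; the background is a flat
    spectrum, so its 800-415 nm band-math difference stays near zero.
    Identical (config, profile, sample_seed) gives a bit-identical cube.
    """
    rng = np.random.default_rng([abs(int(config.seed)), abs(int(sample_seed))])
    wl = config.wavelengths
    endmember = make_endmember(profile, wl)
    mask = _disk_mask(config.image_shape, config.roll_radius_px)
    factor = 1.0 + rng.normal(0.0, config.within_class_sd)
    rows, cols = config.image_shape
    data = np.full((rows, cols, wl.size), config.background_level)
    data[mask] = endmember * factor
    if config.pixel_noise_sd > 0:
        data += rng.normal(0.0, config.pixel_noise_sd, data.shape)
    data = np.clip(data, 0.0, 1.0)
    return SpectralCube(data, wl, kind=REFLECTANCE), mask


def make_reference_pair(
    config: SynthConfig, noise_sd: float = 1e-3
) -> ReferencePair:
    """White (~99.9% reflectance Teflon board) and dark (~0) reference cubes."""
    rng = np.random.default_rng([abs(int(config.seed)), 997])
    rows, cols = config.image_shape
    shape = (rows, cols, config.n_bands)
    wl = config.wavelengths
    white = np.full(shape, 0.999)
    dark = np.zeros(shape)
    if noise_sd > 0:
        white = white + rng.normal(0.0, noise_sd, shape)
        dark = dark + np.abs(rng.normal(0.0, noise_sd, shape))
    return ReferencePair(
        SpectralCube(white, wl, kind=RAW_INTENSITY),
        SpectralCube(dark, wl.copy(), kind=RAW_INTENSITY),
    )


def to_raw_intensity(cube: SpectralCube, refs: ReferencePair) -> SpectralCube:
    """Invert the calibration: I = D + R * (W - D), for end-to-end tests."""
    data = refs.dark.data + cube.data * (refs.white.data - refs.dark.data)
    return SpectralCube(data, cube.wavelengths.copy(), kind=RAW_INTENSITY)


def make_dataset(config: SynthConfig, profiles) -> SpectrumTable:
    """Simulate the extracted mean-spectrum table for a full experiment.

    One mean spectrum per sample: endmember x per-sample factor plus
    residual noise scaled as pixel noise averaged over the roll's pixels.
    The first ``cal_per_class`` samples of each species go to the
    calibration set, the rest to prediction. Defaults give 180 rows,
    120 calibration and 60 prediction.
    """
    profiles = list(profiles)
    species_seen = [p.species for p in profiles]
    if len(set(species_seen)) != len(species_seen):
        raise ConfigError("duplicate species in profiles")
    states = {p.state for p in profiles}
    if len(states) != 1:
        raise ConfigError("all profiles must share one state (raw or cooked)")
    state = states.pop()
    rng = np.random.default_rng([abs(int(config.seed)), 1021])
    wl = config.wavelengths
    n_px = int(_disk_mask(config.image_shape, config.roll_radius_px).sum())
    mean_noise_sd = config.pixel_noise_sd / np.sqrt(n_px)

    spectra, species, sets, ids = [], [], [], []
    for profile in profiles:
        endmember = make_endmember(profile, wl)
        for i in range(config.n_per_class):
            factor = 1.0 + rng.normal(0.0, config.within_class_sd)
            row = endmember * factor + rng.normal(0.0, mean_noise_sd, wl.size)
            spectra.append(np.clip(row, 0.0, 1.0))
            species.append(profile.species)
            sets.append(CAL if i < config.cal_per_class else PRED)
            ids.append(f"{profile.species}_{state}_{i:03d}")
    return SpectrumTable(
        spectra=np.array(spectra),
        wavelengths=wl,
        species=np.array(species),
        state=np.full(len(species), state),
        sets=np.array(sets),
        sample_ids=np.array(ids),
    )
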