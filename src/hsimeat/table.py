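"""Tabular container for extracted sample spectra.

A :class:`SpectrumTable` holds one mean reflectance spectrum per sample
(samples x wavelengths) together with the species label, the raw/cooked
state, and the calibration/prediction set assignment. It round-trips to a
plain CSV with columns ``sample_id, species, state, set`` followed by one
column per wavelength (nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DimensionError

CAL = "cal"
PRED = "pred"


@dataclass
class SpectrumTable:
    spectra: np.ndarray  # (n_samples, n_bands), reflectance fraction
    wavelengths: np.ndarray  # (n_bands,), nm, strictly increasing
    species: np.ndarray  # (n_samples,), str
    state: np.ndarray  # (n_samples,), 'raw' | 'cooked'
    sets: np.ndarray  # (n_samples,), 'cal' | 'pred'
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name in ("species", "state", "sets"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:04d}" for i in range(len(self))])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != self.wavelengths.size:
            raise DimensionError(
                f"spectra {self.spectra.shape} incompatible with "
                f"{self.wavelengths.size} wavelengths"
            )
        n = len(self)
        for name in ("species", "state", "sets", "sample_ids"):
            if len(getattr(self, name)) != n:
                raise DimensionError(f"{name} length != number of spectra")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def class_order(self) -> list:
        """Species labels in first-appearance order (the class codebook order)."""
        seen = []
        for s in self.species:
            if s not in seen:
                seen.append(s)
        return seen

    def rows(self, index: np.ndarray) -> "SpectrumTable":
        return replace(
            self,
            spectra=self.spectra[index],
            species=self.species[index],
            state=self.state[index],
            sets=self.sets[index],
            sample_ids=self.sample_ids[index],
        )

    def calibration(self) -> "SpectrumTable":
        """Rows assigned to the calibration set (all rows if none are tagged)."""
        mask = self.sets == CAL
        return self.rows(mask) if mask.any() else self

    def prediction(self) -> "SpectrumTable":
        mask = self.sets == PRED
        return self.rows(mask)

    def select_bands(self, band_indices) -> "SpectrumTable":
        idx = np.asarray(band_indices, dtype=int)
        return replace(
            self, spectra=self.spectra[:, idx], wavelengths=self.wavelengths[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "species": self.species,
                "state": self.state,
                "set": self.sets,
            }
        )
        spec = pd.DataFrame(
            self.spectra, columns=[f"{w:.4f}" for w in self.wavelengths]
        )
        return pd.concat([meta, spec], axis=1)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectrumTable":
        meta_cols = ["sample_id", "species", "state", "set"]
        wl_cols = [c for c in df.columns if c not in meta_cols]
        return cls(
            spectra=df[wl_cols].to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            species=df["species"].to_numpy(),
            state=df["state"].to_numpy(),
            sets=df["set"].to_numpy(),
            sample_ids=df["sample_id"].to_numpy(),
        )

    @classmethod
    def read_csv(cls, path) -> "SpectrumTable":
        return cls.from_dataframe(pd.read_csv(path))
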