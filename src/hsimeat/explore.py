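"""PCA exploration of extracted spectra and loading-extremum band picking.

Spectra are mean-centred only (no unit-variance scaling: all bands share
reflectance units). Scores of the first two components typically separate
the species clusters; bands where a loading has a strong local extremum
("peaks and valleys" of the loading line) are candidate discriminative
wavelengths, picked by a deterministic rule: strict local extrema of the
absolute loading whose magnitude clears the 80th percentile, pooled over
the requested components, deduplicated within one band, top-n by magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import RankError
from .table import SpectrumTable
from .wavesel import WavelengthSubset


@dataclass
class PCAResult:
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (bands, k), orthonormal columns
    scores: np.ndarray  # (samples, k) = centred data @ loadings
    explained_fraction: np.ndarray  # (k,), non-increasing
    wavelengths: np.ndarray = None


def pca_fit(table: SpectrumTable, k: int) -> PCAResult:
    X = table.spectra
    n, b = X.shape
    if n < 2:
        raise RankError("PCA needs at least two samples")
    if k > min(n - 1, b):
        raise RankError(f"k={k} exceeds min(samples-1, bands)={min(n - 1, b)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        mean_spectrum=pca.mean_,
        loadings=pca.components_.T,
        scores=scores,
        explained_fraction=pca.explained_variance_ratio_,
        wavelengths=table.wavelengths.copy(),
    )


def _local_extrema(v: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima of a non-negative vector."""
    if v.size < 3:
        return np.array([], dtype=int)
    interior = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    return interior


def select_loading_wavelengths(
    result: PCAResult,
    pcs=(1, 2),
    n_top: int = 5,
    percentile: float = 80.0,
) -> WavelengthSubset:
    """Pick the strongest loading extrema of the named PCs (1-indexed)."""
    candidates = []  # (magnitude, band index)
    for pc in pcs:
        if not 1 <= pc <= result.loadings.shape[1]:
            raise RankError(f"PC {pc} was not fitted")
        v = np.abs(result.loadings[:, pc - 1])
        cutoff = np.percentile(v, percentile)
        for idx in _local_extrema(v):
            if v[idx] >= cutoff:
                candidates.append((float(v[idx]), int(idx)))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    picked = []
    for _mag, idx in candidates:
        if len(picked) == n_top:
            break
        if all(abs(idx - p) > 1 for p in picked):  # dedup within +-1 band
            picked.append(idx)
    if len(picked) < n_top:
        warnings.warn(
            f"only {len(picked)} loading extrema found (requested {n_top})",
            stacklevel=2,
        )
    return WavelengthSubset.from_indices(picked, result.wavelengths, "pc")


def plot_scores(result: PCAResult, table: SpectrumTable, path, pcs=(1, 2)) -> None:
    """Score plot of two PCs with 2-sigma covariance ellipses per class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    i, j = pcs[0] - 1, pcs[1] - 1
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in table.class_order:
        pts = result.scores[table.species == cls][:, [i, j]]
        (line,) = ax.plot(pts[:, 0], pts[:, 1], "o", ms=4, label=cls, alpha=0.7)
        if len(pts) > 2:
            cov = np.cov(pts.T)
            vals, vecs = np.linalg.eigh(cov)
            angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
            ax.add_patch(Ellipse(
                pts.mean(axis=0), 4 * np.sqrt(vals[-1]), 4 * np.sqrt(vals[0]),
                angle=angle, fill=False, color=line.get_color(), lw=1,
            ))
    ax.set_xlabel(f"PC{pcs[0]} ({result.explained_fraction[i]:.1%})")
    ax.set_ylabel(f"PC{pcs[1]} ({result.explained_fraction[j]:.1%})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loadings(result: PCAResult, path, pcs=(1, 2)) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for pc in pcs:
        ax.plot(result.wavelengths, result.loadings[:, pc - 1], label=f"PC{pc}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("loading")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
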