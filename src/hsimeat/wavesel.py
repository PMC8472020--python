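"""Wavelength selection: SPA, random frog, and simulated annealing.

All three selectors share one evaluation criterion so that their outputs are
comparable: the venetian-blinds cross-validated misclassification rate of a
PLS-DA fitted on the candidate bands (with a fixed latent-variable count of
min(n_bands, n_classes)). Scores are cached per subset, so the stochastic
searches revisit states cheaply.

* SPA (successive projections algorithm) is deterministic: from every start
  band it grows a chain where the next variable is the column of largest
  norm after projecting all columns onto the orthogonal complement of the
  span of the chain so far; every chain prefix with length in
  [n_min, n_max] is a candidate subset, and the candidate with the lowest
  criterion wins (ties: fewer bands, then lower indices).
* Random frog runs a seeded subset-chain: a candidate subset of a size
  drawn around the current size is proposed each iteration and accepted
  outright when better, else with a ratio probability softened by ``eta``;
  the per-band selection frequency over the iterations is the output, and
  bands clearing the frequency rule form the subset.
* Simulated annealing walks over subsets with swap (and, for free size,
  grow/shrink) moves, always accepting improvements and accepting worse
  moves with probability exp(-dE/T) under the geometric schedule
  T_k = t_init * cooling_rate^k; the best state ever visited is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .models import plsda_cv_error
from .table import SpectrumTable


@dataclass
class SPAConfig:
    n_min: int = 1
    n_max: int = 10

    def __post_init__(self):
        if not 1 <= self.n_min <= self.n_max:
            raise ConfigError("need 1 <= n_min <= n_max")


@dataclass
class RFConfig:
    n_iterations: int = 1000
    q_init: int = 2
    theta: float = 0.3  # sd of the proposed subset size, as a fraction of Q
    eta: float = 0.1  # softening factor on the acceptance ratio
    seed: int = 0
    frequency_cutoff: float = 0.25
    max_selected: int = 8

    def __post_init__(self):
        if self.n_iterations < 1 or self.q_init < 1:
            raise ConfigError("n_iterations and q_init must be >= 1")
        if self.n_iterations < 100:
            warnings.warn("random frog with < 100 iterations is below any "
                          "reasonable burn-in", stacklevel=2)


@dataclass
class SAAConfig:
    t_init: float = 50.0
    cooling_rate: float = 0.96
    moves_per_temperature: int = 20
    t_stop: float = 0.01
    subset_size: int | str = "free"  # fixed integer, or "free" with bounds
    size_bounds: tuple = (1, 10)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.cooling_rate < 1:
            raise ConfigError("cooling_rate must lie in (0, 1)")
        if self.t_stop >= self.t_init:
            raise ConfigError("t_stop must be below t_init")


@dataclass
class WavelengthSubset:
    """A selected set of bands plus the method and criterion score."""

    band_indices: np.ndarray
    wavelengths_nm: np.ndarray
    method: str  # 'spa' | 'rf' | 'saa' | 'pc' | 'full'
    score: float | None = None

    def __post_init__(self):
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.band_indices.size != np.unique(self.band_indices).size:
            raise ConfigError("band indices must be unique")
        order = np.argsort(self.band_indices)
        self.band_indices = self.band_indices[order]
        self.wavelengths_nm = self.wavelengths_nm[order]

    def __len__(self) -> int:
        return self.band_indices.size

    @classmethod
    def from_indices(cls, indices, wavelengths, method, score=None):
        idx = np.asarray(sorted(indices), dtype=int)
        return cls(idx, np.asarray(wavelengths, dtype=float)[idx], method, score)


class SubsetScorer:
    """Cached shared criterion: CV misclassification of PLS-DA on a subset."""

    def __init__(self, table: SpectrumTable, n_splits: int = 10):
        cal = table.calibration()
        self.X = cal.spectra
        self.y = cal.species
        self.n_classes = len(cal.class_order)
        self.n_splits = n_splits
        self._cache: dict = {}
        self.n_evaluations = 0

    def __call__(self, indices) -> float:
        key = frozenset(int(i) for i in indices)
        if key not in self._cache:
            idx = np.asarray(sorted(key), dtype=int)
            n_lvs = min(idx.size, self.n_classes)
            self._cache[key] = plsda_cv_error(
                self.X[:, idx], self.y, n_lvs, self.n_splits
            )
            self.n_evaluations += 1
        return self._cache[key]


# ---------------------------------------------------------------------------
# SPA


def spa_chain(X: np.ndarray, start: int, n_max: int, tol: float = 1e-12) -> list:
    """Projection chain from one start column (successive projections).

    At each step every remaining column is projected onto the orthogonal
    complement of the span of the chain; the column with the largest
    remaining norm joins next (ties break toward the lower index).
    Zero-norm (collinear) columns are never selected.
    """
    P = np.asarray(X, dtype=float).copy()
    chain = [int(start)]
    for _ in range(n_max - 1):
        v = P[:, chain[-1]].copy()
        nv = v @ v
        if nv < tol:
            break
        P -= np.outer(v, v @ P) / nv
        norms = np.einsum("ij,ij->j", P, P)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= tol:
            break
        chain.append(nxt)
    return chain


def spa_select(
    table: SpectrumTable, config: SPAConfig | None = None, n_splits: int = 10
) -> WavelengthSubset:
    """Deterministic SPA selection over all start bands and chain lengths."""
    config = config or SPAConfig()
    cal = table.calibration()
    Xc = cal.spectra - cal.spectra.mean(axis=0)
    n_bands = Xc.shape[1]
    if config.n_max > n_bands:
        raise ConfigError("n_max exceeds the number of bands")
    scorer = SubsetScorer(table, n_splits)
    best = None  # (score, size, indices tuple)
    for start in range(n_bands):
        chain = spa_chain(Xc, start, config.n_max)
        for n in range(config.n_min, min(config.n_max, len(chain)) + 1):
            subset = tuple(sorted(chain[:n]))
            cand = (scorer(subset), len(subset), subset)
            if best is None or cand < best:
                best = cand
    score, _, subset = best
    return WavelengthSubset.from_indices(subset, table.wavelengths, "spa", score)


# ---------------------------------------------------------------------------
# Random frog


def rf_select(
    table: SpectrumTable, config: RFConfig | None = None, n_splits: int = 10
):
    """Random-frog subset chain; returns (per-band frequency, subset)."""
    config = config or RFConfig()
    rng = np.random.default_rng(abs(int(config.seed)))
    n_bands = table.n_bands
    scorer = SubsetScorer(table, n_splits)
    all_bands = np.arange(n_bands)

    current = set(rng.choice(n_bands, size=min(config.q_init, n_bands),
                             replace=False).tolist())
    current_err = scorer(current)
    counts = np.zeros(n_bands)
    for _ in range(config.n_iterations):
        q = len(current)
        q_star = int(np.clip(round(rng.normal(q, config.theta * q)), 1, n_bands))
        members = np.array(sorted(current))
        outside = np.setdiff1d(all_bands, members, assume_unique=True)
        candidate = set(current)
        if q_star < q:
            drop = rng.choice(members, size=q - q_star, replace=False)
            candidate -= set(drop.tolist())
        elif q_star > q:
            add = rng.choice(outside, size=min(q_star - q, outside.size),
                             replace=False)
            candidate |= set(add.tolist())
        elif outside.size:  # same size: swap one member for one non-member
            candidate.discard(int(rng.choice(members)))
            candidate.add(int(rng.choice(outside)))
        cand_err = scorer(candidate)
        if cand_err <= current_err:
            accept = True
        else:
            # ratio-based probability softened by eta (worse subsets rarely kept)
            accept = rng.random() < config.eta * current_err / cand_err
        if accept:
            current, current_err = candidate, cand_err
        counts[sorted(current)] += 1

    frequency = counts / config.n_iterations
    chosen = np.flatnonzero(frequency >= config.frequency_cutoff)
    if chosen.size == 0:
        chosen = np.argsort(-frequency, kind="stable")[: config.q_init]
    elif chosen.size > config.max_selected:
        order = np.lexsort((chosen, -frequency[chosen]))
        chosen = chosen[order][: config.max_selected]
    subset = WavelengthSubset.from_indices(
        chosen, table.wavelengths, "rf", scorer(chosen)
    )
    return frequency, subset


# ---------------------------------------------------------------------------
# Simulated annealing


def saa_select(
    table: SpectrumTable, config: SAAConfig | None = None, n_splits: int = 10,
    trace: list | None = None,
) -> WavelengthSubset:
    """Simulated-annealing subset search returning the best-ever state."""
    config = config or SAAConfig()
    rng = np.random.default_rng(abs(int(config.seed)))
    n_bands = table.n_bands
    scorer = SubsetScorer(table, n_splits)
    all_bands = np.arange(n_bands)

    free = config.subset_size == "free"
    lo, hi = config.size_bounds if free else (config.subset_size, config.subset_size)
    hi = min(hi, n_bands)
    q0 = min(3, hi) if free else int(config.subset_size)
    state = set(rng.choice(n_bands, size=q0, replace=False).tolist())
    energy = scorer(state)
    best_state, best_energy = set(state), energy

    T = config.t_init
    while T > config.t_stop:
        for _ in range(config.moves_per_temperature):
            members = np.array(sorted(state))
            outside = np.setdiff1d(all_bands, members, assume_unique=True)
            moves = ["swap"]
            if free and len(state) < hi and outside.size:
                moves.append("grow")
            if free and len(state) > lo:
                moves.append("shrink")
            move = moves[rng.integers(len(moves))]
            candidate = set(state)
            if move == "swap" and outside.size:
                candidate.discard(int(rng.choice(members)))
                candidate.add(int(rng.choice(outside)))
            elif move == "grow":
                candidate.add(int(rng.choice(outside)))
            elif move == "shrink":
                candidate.discard(int(rng.choice(members)))
            if candidate == state:
                continue
            d_energy = scorer(candidate) - energy
            if d_energy <= 0 or rng.random() < np.exp(-d_energy / T):
                state = candidate
                energy += d_energy
                if energy < best_energy:
                    best_state, best_energy = set(state), energy
            if trace is not None:
                trace.append((T, energy, best_energy))
        T *= config.cooling_rate
    return WavelengthSubset.from_indices(
        best_state, table.wavelengths, "saa", best_energy
    )


# ---------------------------------------------------------------------------


def full_subset(table: SpectrumTable) -> WavelengthSubset:
    """The identity selection: every band of the table."""
    return WavelengthSubset.from_indices(
        np.arange(table.n_bands), table.wavelengths, "full"
    )


def reduction_percent(n_full: int, n_selected: int) -> float:
    """Dimensionality reduction 100 * (n_full - n_selected) / n_full, one decimal."""
    if n_full < 1 or not 0 <= n_selected <= n_full:
        raise ConfigError("need 0 <= n_selected <= n_full and n_full >= 1")
    return round(100.0 * (n_full - n_selected) / n_full, 1)
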