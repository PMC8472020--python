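"""Wavelength selectors: SPA chains, random frog, simulated annealing."""

import numpy as np
import pytest

import hsimeat as h
from hsimeat.errors import ConfigError
from hsimeat.wavesel import (
    RFConfig,
    SAAConfig,
    SPAConfig,
    SubsetScorer,
    spa_chain,
)


def gram_schmidt_chain(X, start, n_max):
    """Explicit orthogonalization oracle for the SPA projection chain."""
    X = np.asarray(X, dtype=float)
    chain = [start]
    basis = []
    for _ in range(n_max - 1):
        v = X[:, chain[-1]].copy()
        for b in basis:
            v -= (v @ b) * b
        if v @ v < 1e-12:
            break
        basis.append(v / np.linalg.norm(v))
        norms = []
        for j in range(X.shape[1]):
            if j in chain:
                norms.append(-1.0)
                continue
            r = X[:, j].copy()
            for b in basis:
                r -= (r @ b) * b
            norms.append(r @ r)
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-12:
            break
        chain.append(nxt)
    return chain


class TestSpaChain:
    def test_orthogonal_columns_pick_largest_norm(self):
        X = np.diag([1.0, 3.0, 2.0, 5.0])
        for start in range(4):
            chain = spa_chain(X, start, 2)
            remaining = [j for j in range(4) if j != start]
            best = max(remaining, key=lambda j: np.linalg.norm(X[:, j]))
            assert chain[1] == best

    def test_duplicated_column_never_selected_twice(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 5))
        X[:, 4] = X[:, 1]  # exact duplicate
        chain = spa_chain(X, 1, 5)
        assert 4 not in chain

    def test_matches_gram_schmidt_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 6))
        for start in range(6):
            assert spa_chain(X, start, 6) == gram_schmidt_chain(X, start, 6)


class TestSpaSelect:
    def test_deterministic(self, make_informative_table):
        table = make_informative_table(seed=5)
        a = h.spa_select(table, SPAConfig(n_min=1, n_max=4))
        b = h.spa_select(table, SPAConfig(n_min=1, n_max=4))
        np.testing.assert_array_equal(a.band_indices, b.band_indices)

    def test_finds_informative_neighbourhood(self, make_informative_table):
        table = make_informative_table(seed=6, informative=(12, 30))
        subset = h.spa_select(table, SPAConfig(n_min=1, n_max=4))
        hits = {b for b in subset.band_indices
                for info in (12, 30) if abs(b - info) <= 2}
        assert hits

    def test_n_max_exceeding_bands_rejected(self, make_informative_table):
        table = make_informative_table(seed=0, n_bands=5, informative=(2,))
        with pytest.raises(ConfigError):
            h.spa_select(table, SPAConfig(n_min=1, n_max=10))


class TestRandomFrog:
    def test_frequencies_in_unit_interval(self, make_informative_table):
        table = make_informative_table(seed=7, n_bands=12, informative=(5,))
        freq, subset = h.rf_select(table, RFConfig(n_iterations=200, seed=1),
                                   n_splits=5)
        assert np.all((freq >= 0) & (freq <= 1))
        assert len(subset) >= 1

    def test_same_seed_identical_frequencies(self, make_informative_table):
        table = make_informative_table(seed=8, n_bands=12, informative=(5,))
        f1, _ = h.rf_select(table, RFConfig(n_iterations=300, seed=4), n_splits=5)
        f2, _ = h.rf_select(table, RFConfig(n_iterations=300, seed=4), n_splits=5)
        np.testing.assert_array_equal(f1, f2)

    def test_informative_band_outranks_noise(self, make_informative_table):
        """Band 5 alone determines the class; over 20 seeds its selection
        frequency must beat the median noise-band frequency >= 95% of runs."""
        successes = 0
        for seed in range(20):
            table = make_informative_table(
                seed=100 + seed, n_bands=10, informative=(5,),
                n_per_class=8, n_classes=2,
            )
            freq, _ = h.rf_select(table, RFConfig(n_iterations=1000, seed=seed),
                                  n_splits=5)
            noise = np.delete(freq, 5)
            successes += freq[5] > np.median(noise)
        assert successes >= 19

    def test_short_chain_warns(self, make_informative_table):
        with pytest.warns(UserWarning):
            RFConfig(n_iterations=50)


class TestSimulatedAnnealing:
    def test_temperature_schedule_arithmetic(self):
        config = SAAConfig()
        t = config.t_init
        for _ in range(10):
            t *= config.cooling_rate
        assert t == pytest.approx(50 * 0.96**10)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SAAConfig(t_stop=60.0)
        with pytest.raises(ConfigError):
            SAAConfig(cooling_rate=1.1)

    def test_seeded_determinism(self, make_informative_table):
        table = make_informative_table(seed=9, n_bands=12, informative=(4, 8))
        config = SAAConfig(seed=11, t_init=1.0, t_stop=0.05)
        a = h.saa_select(table, config, n_splits=5)
        b = h.saa_select(table, config, n_splits=5)
        np.testing.assert_array_equal(a.band_indices, b.band_indices)

    def test_trace_records_monotone_best(self, make_informative_table):
        table = make_informative_table(seed=10, n_bands=12, informative=(4,))
        trace = []
        h.saa_select(table, SAAConfig(seed=3, t_init=1.0, t_stop=0.1),
                     n_splits=5, trace=trace)
        best = [t[2] for t in trace]
        assert all(b1 >= b2 for b1, b2 in zip(best, best[1:]))


class TestSharedCriterion:
    def test_selected_beats_random_subsets(self, make_informative_table):
        """Each selector's score is no worse than the median random subset
        of the same size on data with informative bands."""
        table = make_informative_table(seed=12)
        scorer = SubsetScorer(table, n_splits=5)
        rng = np.random.default_rng(0)
        for subset in (
            h.spa_select(table, SPAConfig(1, 3), n_splits=5),
            h.rf_select(table, RFConfig(n_iterations=300, seed=2), n_splits=5)[1],
            h.saa_select(table, SAAConfig(seed=2, t_init=1.0, t_stop=0.05),
                         n_splits=5),
        ):
            random_scores = [
                scorer(rng.choice(table.n_bands, size=len(subset), replace=False))
                for _ in range(20)
            ]
            assert subset.score <= np.median(random_scores)


class TestReductionPercent:
    @pytest.mark.parametrize("n_full,n_sel,expected", [
        (285, 3, 98.9),
        (285, 8, 97.2),
        (10, 10, 0.0),
    ])
    def test_values(self, n_full, n_sel, expected):
        assert h.reduction_percent(n_full, n_sel) == expected

    def test_domain_errors(self):
        with pytest.raises(ConfigError):
            h.reduction_percent(10, 11)
        with pytest.raises(ConfigError):
            h.reduction_percent(0, 0)


class TestWavelengthSubset:
    def test_indices_sorted_and_matched(self):
        wl = np.linspace(400, 1000, 20)
        subset = h.WavelengthSubset.from_indices([7, 3, 15], wl, "spa")
        assert subset.band_indices.tolist() == [3, 7, 15]
        np.testing.assert_array_equal(subset.wavelengths_nm, wl[[3, 7, 15]])

    def test_duplicate_indices_rejected(self):
        wl = np.linspace(400, 1000, 20)
        with pytest.raises(ConfigError):
            h.WavelengthSubset(np.array([3, 3]), wl[[3, 3]], "spa")
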