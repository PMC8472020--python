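import numpy as np
import pytest

import hsimeat as h


@pytest.fixture(scope="session")
def synth_config():
    return h.SynthConfig(seed=0)


@pytest.fixture(scope="session")
def raw_profiles():
    return h.default_profiles("raw")


@pytest.fixture(scope="session")
def raw_table(synth_config, raw_profiles):
    """Default synthetic raw-state dataset, trimmed to 400-1000 nm."""
    table = h.make_dataset(synth_config, raw_profiles.values())
    return h.trim_spectral(table, 400.0, 1000.0)


def informative_table(
    seed: int,
    n_bands: int = 40,
    informative=(12, 30),
    n_per_class: int = 20,
    delta: float = 0.15,
    noise: float = 0.02,
    n_classes: int = 3,
):
    """Synthetic spectrum table whose classes differ only at known bands.

    Every band is flat baseline + noise; each class adds its own offset at
    the informative bands only, so any selector that works must touch their
    neighbourhood.
    """
    rng = np.random.default_rng(seed)
    classes = ["mutton", "pork", "duck"][:n_classes]
    rows, labels = [], []
    for c_idx, cls in enumerate(classes):
        for _ in range(n_per_class):
            row = 0.4 + rng.normal(0, noise, n_bands)
            for b_idx, band in enumerate(informative):
                row[band] += delta * (c_idx - 1) * (1 if b_idx % 2 == 0 else -1)
            rows.append(row)
            labels.append(cls)
    n = len(rows)
    return h.SpectrumTable(
        spectra=np.array(rows),
        wavelengths=np.linspace(400, 1000, n_bands),
        species=np.array(labels),
        state=np.full(n, "raw"),
        sets=np.full(n, "cal"),
    )


@pytest.fixture
def make_informative_table():
    return informative_table
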