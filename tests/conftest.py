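import numpy as np
import pytest

from cottongs.data_io import GenotypeMatrix
from cottongs.simulate import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genotypes(rng):
    """Small complete dosage matrix (8 lines x 12 polymorphic markers)."""
    M = rng.binomial(2, 0.4, size=(8, 12)).astype(float)
    # make sure every marker is polymorphic
    M[0] = (M[0] + 1) % 3
    return GenotypeMatrix([f"L{i}" for i in range(8)],
                          [f"M{k}" for k in range(12)],
                          M, np.zeros((8, 12), bool))


@pytest.fixture(scope="session")
def small_single_site():
    """One-site simulated dataset with ground truth (session-cached)."""
    cfg = SimConfig(n_lines=80, n_markers=120, n_sites=1, pi_nonnull=0.3,
                    h2_target=0.5, var_site=0.0, missing_rate=0.0, seed=77)
    g, phen, truth = simulate_dataset(cfg)
    y = phen.records["mean"].to_numpy()
    y = (y - y.mean()) / y.std(ddof=1)
    return g, truth.X, y, truth


@pytest.fixture(scope="session")
def multisite_sim():
    """Four-site simulated dataset with genuine site-specific effects."""
    cfg = SimConfig(n_lines=100, n_markers=200, n_sites=4, pi_nonnull=0.3,
                    var_main=1.0, var_site=0.5, h2_target=(0.6, 0.5, 0.4, 0.3),
                    missing_rate=0.0, seed=55)
    return simulate_dataset(cfg)
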