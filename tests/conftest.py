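import numpy as np
import pytest

from camkii_ensemble import (ALPHA_LIKE, BETA_LIKE, SimulationConfig,
                             measure_particles, simulate_ensemble)


@pytest.fixture(scope="session")
def beta_noiseless_ensemble():
    """1000 beta-like particles, pure 12-mer, no noise/dimers/compacts."""
    cfg = BETA_LIKE.with_(noise_sd=0.0, dimer_fraction=0.0,
                          compact_fraction=0.0,
                          stoichiometry_mix={12: 1.0})
    return simulate_ensemble(cfg, 1000, seed=42)


@pytest.fixture(scope="session")
def beta_measurements(beta_noiseless_ensemble):
    return measure_particles(beta_noiseless_ensemble)


@pytest.fixture(scope="session")
def alpha_small_ensemble():
    """200 alpha-like particles at default (pixel-scale) noise."""
    return simulate_ensemble(ALPHA_LIKE, 200, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def pure_config():
    """Single-stoichiometry noiseless config factory."""
    def make(stoich=12, **kw):
        base = dict(stoichiometry_mix={stoich: 1.0}, noise_sd=0.0,
                    dimer_fraction=0.0, compact_fraction=0.0,
                    radius_mean=16.8, radius_sd=3.3)
        base.update(kw)
        return SimulationConfig(**base)
    return make
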