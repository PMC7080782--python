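import numpy as np
import pytest

from assemblage.io import Experiment, MicrocosmSeries
from assemblage.synthetic import SyntheticConfig, generate_experiment


def make_series(presence, microcosm_id="M01", treatment="filtered",
                inoculum_id=None, interval=3, scale=100):
    """Build a MicrocosmSeries from a {asv: [transfer indices present]} layout
    over transfers 0..21 (days 0..63)."""
    asvs = sorted(presence)
    days = np.arange(22) * interval
    counts = np.zeros((22, len(asvs)), dtype=int)
    for j, asv in enumerate(asvs):
        for t in presence[asv]:
            counts[t, j] = scale
    return MicrocosmSeries(microcosm_id=microcosm_id,
                           inoculum_id=inoculum_id or microcosm_id,
                           treatment=treatment, days=days, asv_ids=asvs,
                           counts=counts)


@pytest.fixture
def toy_experiment():
    s1 = make_series({"a": range(22), "b": [0, 1, 2, 3], "c": range(22)}, "M01")
    s2 = make_series({"a": range(22), "b": range(22), "d": [0, 1]}, "M02")
    return Experiment(series=[s1, s2])


@pytest.fixture(scope="session")
def default_synthetic():
    """One synthetic experiment at study-design defaults, shared per session."""
    return generate_experiment(SyntheticConfig(rng_seed=0))


@pytest.fixture(scope="session")
def small_config():
    """Reduced design for faster end-to-end tests (same dynamics)."""
    return SyntheticConfig(n_inocula=5, pool_size=120,
                           initial_richness_range=(15, 40),
                           read_depth=20000, rng_seed=0)
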