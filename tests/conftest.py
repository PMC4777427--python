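import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genevidence import scenarios
from genevidence.simulate import NeighborhoodSpec, simulate_neighborhood

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """One unfragmented simulated neighborhood (record, truth)."""
    return simulate_neighborhood(NeighborhoodSpec(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A smaller 3-exon simulation for fast alignment checks."""
    spec = NeighborhoodSpec(
        seed=7, target_exon_count=3, target_protein_length=60,
        intergenic_length=400, margin_length=300,
    )
    return simulate_neighborhood(spec)


@pytest.fixture(scope="session")
def ground_tit():
    return scenarios.ground_tit_like(0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160303)
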