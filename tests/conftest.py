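import numpy as np
import pytest

from taunet.network import network_measures
from taunet.synthetic import SimulationConfig, make_phantom_atlas, simulate_profiles


@pytest.fixture(scope="session")
def small_atlas():
    """An 8-region phantom atlas on a 48^3 grid at 2 mm."""
    return make_phantom_atlas(grid=(48, 48, 48), k=8, seed=11)


@pytest.fixture(scope="session")
def cohort_atlas():
    """A 64-region phantom atlas, matching the scale of a real parcellation."""
    return make_phantom_atlas(grid=(64, 64, 64), k=64, seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_atlas):
    """200 simulated subjects with their network measures."""
    config = SimulationConfig(n_subjects=200, seed=12)
    profiles, severities = simulate_profiles(cohort_atlas, config)
    measures = [
        network_measures(p, limbic_ids=cohort_atlas.limbic_ids) for p in profiles
    ]
    return profiles, severities, measures


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
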