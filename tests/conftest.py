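import pytest
from hypothesis import HealthCheck, settings

from proloop import AlignmentSimConfig, random_species_tree, simulate_alignment

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_default():
    """Zero-noise synthetic pLGIC alignment at the survey's composition."""
    return simulate_alignment(AlignmentSimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    counts = {
        "metazoa_cys_loop_anionic": 6,
        "metazoa_cys_loop_cationic": 6,
        "metazoa_cys_less": 4,
        "bacteria": 8,
        "archaea": 2,
        "protist_cys_less": 4,
        "protist_cys_loop": 2,
    }
    return simulate_alignment(AlignmentSimConfig(counts=counts, seed=5))


@pytest.fixture(scope="session")
def species10():
    return random_species_tree(10, seed=42)
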