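import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

# make tests/oracles.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_truth():
    """A small planted simulation shared by delineation/pipeline tests."""
    from taxodelim.simulate import SimParams, evolve_proteomes, simulate_tree

    params = SimParams(n_families=4, n_proteins=6, protein_length=(120, 160), seed=11)
    truth = simulate_tree(params)
    proteomes = evolve_proteomes(truth)
    return truth, proteomes


@pytest.fixture(scope="session")
def small_aai(small_truth):
    from taxodelim.aai import aai_matrix

    _truth, proteomes = small_truth
    return aai_matrix(proteomes)
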