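import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from swigh import SimulationConfig, make_toy_references, simulate_library


@pytest.fixture(scope="session")
def toy_refs():
    return make_toy_references(5, 3, seed=1)


@pytest.fixture(scope="session")
def diagnostic_library(toy_refs):
    """Error-free library in the diagnostic regime: dominant clone at 0.85."""
    cfg = SimulationConfig(
        n_reads=5000, refs=toy_refs, clonal_fraction=0.85, seed=11
    )
    return simulate_library(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
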