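import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import brainnet as bn


@pytest.fixture(scope="session")
def aal() -> bn.RegionAtlas:
    return bn.default_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (N=20 regions, short runs) for fast pipeline tests."""
    spec = bn.GroundTruthSpec(
        n_regions=20,
        n_timepoints=200,
        base_degree=4,
        hub_regions=(0, 10),
        hub_extra_degree=6,
        n_modules=2,
        seed=11,
    )
    return spec, bn.simulate_cohort(spec, 4)


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric Bernoulli adjacency with empty diagonal."""
    A = rng.random((n, n)) < p
    A = np.triu(A, 1)
    return A | A.T
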