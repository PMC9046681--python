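import numpy as np
import pytest

from icfscale.matrices import BinaryResponseMatrix
from icfscale.synthetic import ItemSpec, SimulationConfig, simulate_dichotomous


def rasch_items(difficulties, discrimination=1.0, prefix="i"):
    return [
        ItemSpec(f"{prefix}{j + 1:02d}", float(b), discrimination)
        for j, b in enumerate(difficulties)
    ]


def simulate_rasch(difficulties, n, seed, discrimination=1.0):
    cfg = SimulationConfig(
        n_persons=n, items=rasch_items(difficulties, discrimination), seed=seed
    )
    return simulate_dichotomous(cfg)


@pytest.fixture(scope="session")
def rasch_cohort():
    """1000 persons x 10 Rasch items on an evenly spaced difficulty grid."""
    return simulate_rasch(np.arange(-2.25, 2.26, 0.5), n=1000, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_binary_matrix(rng, n=20, k=8):
    """A random matrix guaranteed to have no constant items."""
    while True:
        values = (rng.random((n, k)) < rng.uniform(0.2, 0.8, size=k)).astype(int)
        pop = values.mean(axis=0)
        if ((pop > 0) & (pop < 1)).all():
            return BinaryResponseMatrix(values)
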