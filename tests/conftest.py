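import numpy as np
import pandas as pd
import pytest

from rileqtl import simulate as sim
from rileqtl.scan import genotype_probabilities
from rileqtl.types import GeneticMap, RilGenotypes


@pytest.fixture(scope="session")
def toy_map():
    markers = pd.DataFrame(
        {"chrom": ["1"] * 3, "cm": [0.0, 10.0, 20.0], "bp": [1, 100_000, 200_000]},
        index=pd.Index(["m1", "m2", "m3"], name="marker"),
    )
    return GeneticMap(markers, {"1": 200_000})


@pytest.fixture(scope="session")
def toy_cross(toy_map):
    """8 lines, fully observed: 4 Col, 4 Alt across the chromosome."""
    calls = np.array([[0, 0, 0]] * 4 + [[1, 1, 1]] * 4, dtype=np.int8)
    genos = RilGenotypes([f"L{i + 1}" for i in range(8)], calls, toy_map)
    return toy_map, genos


@pytest.fixture(scope="session")
def toy_probs(toy_cross):
    gmap, genos = toy_cross
    return genotype_probabilities(gmap, genos, step=2.0)


@pytest.fixture(scope="session")
def toy_trait():
    return np.array([1, 1, 1, 0, 0, 0, 0, 1], dtype=float)


@pytest.fixture(scope="session")
def study_cross():
    """A cross at the study scale: 5 chromosomes, 90 markers, 158 lines."""
    gmap = sim.default_map()
    genos = sim.simulate_ril_genotypes(gmap, 158, seed=11)
    return gmap, genos


@pytest.fixture(scope="session")
def study_probs(study_cross):
    gmap, genos = study_cross
    return genotype_probabilities(gmap, genos, step=2.0)
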