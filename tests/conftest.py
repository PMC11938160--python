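import numpy as np
import pytest

from glycoscape.glycans import default_taxonomy
from glycoscape.simulate import (
    SimulationConfig,
    build_glycan_library,
    random_structure,
    simulate_study,
)


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def library(taxonomy):
    return build_glycan_library(taxonomy)


@pytest.fixture(scope="session")
def random_structures(taxonomy):
    """1,000 random valid structures, fixed seed."""
    rng = np.random.default_rng(20240901)
    return [random_structure(rng, taxonomy) for _ in range(1000)]


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 42), shared across tests."""
    return simulate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_study_dir(default_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    paths = default_study.write(out)
    return paths
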