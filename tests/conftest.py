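import numpy as np
import pytest

import unigev as ug
from unigev.codon_model import STANDARD_CODE


@pytest.fixture(scope="session")
def ibmoi_us():
    """Published unselected-pool misincorporation counts (87 clones)."""
    return ug.load_ibmoi_counts("unselected")


@pytest.fixture(scope="session")
def ibmoi_mx():
    return ug.load_ibmoi_counts("selected")


@pytest.fixture(scope="session")
def table_P(ibmoi_us):
    """Natural-parameter mutation-matrix estimate from the unselected counts."""
    return ug.natural_parameter_matrix(ibmoi_us)


@pytest.fixture(scope="session")
def ibmoi_map(ibmoi_us):
    """MAP polymerase fit (k=30) to the unselected counts; shared: it is
    deterministic and moderately expensive."""
    return ug.map_estimate(ibmoi_us, 30)


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


def random_stochastic_matrix(rng: np.random.Generator, dim: int = 4) -> np.ndarray:
    """Random column-stochastic matrix (uniform Dirichlet columns)."""
    return rng.dirichlet(np.ones(dim), size=dim).T
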