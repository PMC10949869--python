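import numpy as np
import pytest

from vittabo.cohort import PhenotypeCounts
from vittabo.simulate import reference_cohort


@pytest.fixture(scope="session")
def vaccinated_counts() -> PhenotypeCounts:
    """Blood-type counts of the 47 Definite/Probable vaccinated cases."""
    return PhenotypeCounts(nO=20, nA=22, nB=2, nAB=3)


@pytest.fixture(scope="session")
def unvaccinated_counts() -> PhenotypeCounts:
    """Blood-type counts of the 441 unvaccinated controls."""
    return PhenotypeCounts(nO=74, nA=312, nB=39, nAB=16)


@pytest.fixture(scope="session")
def cohort():
    """The deterministic 523-subject reference cohort."""
    return reference_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
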