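import logging

import numpy as np
import pytest

from metaerf.basis import CrossBasisSpec
from metaerf.synthetic import StudyConfig, gen_study

logging.getLogger("metaerf").setLevel(logging.ERROR)
logging.getLogger("metaerf.first_stage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    return gen_study(StudyConfig(n_locations=14, years=2, seed=101))


@pytest.fixture(scope="session")
def resolved_spec(rng):
    x = rng.normal(18, 7, 2000)
    return CrossBasisSpec().resolve(x), x
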