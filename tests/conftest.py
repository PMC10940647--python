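import numpy as np
import pytest

from weedrot import density_model as dm
from weedrot import econmod as em
from weedrot import strategies as st
from weedrot import synthetic_data as sd


@pytest.fixture(scope="session")
def prices():
    return em.PriceTable.load_default()


@pytest.fixture(scope="session")
def base_yields():
    return em.BaseYieldTable.load_default()


@pytest.fixture(scope="session")
def penalties():
    return em.YieldPenaltyTable.load_default()


@pytest.fixture(scope="session")
def bau():
    return st.build_bau()


@pytest.fixture(scope="session")
def cww():
    return st.build_cww()


@pytest.fixture(scope="session")
def mit_strategies():
    return st.load_default_mit_strategies()


@pytest.fixture(scope="session")
def small_survey_data():
    cfg = sd.SyntheticConfig(seed=11, n_fields=40, grid_dims=(8, 8))
    return sd.gen_survey_data(cfg)


@pytest.fixture(scope="session")
def zero_model():
    """Cumulative-logit model with all coefficients zero."""
    return dm.make_known_model(cutpoints=(-2.0, -1.0, 1.0, 2.0))


@pytest.fixture(scope="session")
def effective_model():
    """Generating model in which cultural controls suppress density."""
    return sd.default_true_model(seed=0)


@pytest.fixture(scope="session")
def toy_distribution():
    return np.array([0.1, 0.1, 0.2, 0.3, 0.3])
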