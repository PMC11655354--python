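import warnings

import numpy as np
import pandas as pd
import pytest

from extremesoil.design import build_design, records_to_frame


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """Mixed-model boundary warnings and vacuous-exclusion warnings are
    expected throughout; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_design():
    """4 countries x 3 sites: enough structure for random effects, fast."""
    return build_design(n_countries=4)


@pytest.fixture(scope="session")
def small_metadata(small_design):
    return records_to_frame(small_design.records("amplicon"))


@pytest.fixture(scope="session")
def full_design():
    return build_design()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def random_counts():
    gen = np.random.default_rng(42)
    return pd.DataFrame(
        gen.integers(1, 60, size=(10, 8)),
        index=[f"s{i}" for i in range(10)],
        columns=[f"f{j}" for j in range(8)],
    )
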