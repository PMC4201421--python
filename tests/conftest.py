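import numpy as np
import pandas as pd
import pytest

import fecvar
from fecvar import Dataset, MCMCSettings


@pytest.fixture(scope="session")
def tiny_df() -> pd.DataFrame:
    """2 lines x 1 block x 1 food x 3 replicates."""
    return pd.DataFrame(
        {
            "line_id": ["A"] * 3 + ["B"] * 3,
            "block": 1,
            "food": "e_coli",
            "replicate": [1, 2, 3, 1, 2, 3],
            "lifetime_fecundity": [10, 20, 30, 200, 250, 300],
        }
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_df) -> Dataset:
    return Dataset(tiny_df)


@pytest.fixture(scope="session")
def bp_data() -> Dataset:
    """One study-scale synthetic food environment (21 x 3 x 5 = 315 obs)."""
    return fecvar.generate_dataset(fecvar.study_config("b_pumilus"), seed=11)


@pytest.fixture(scope="session")
def bp_fit2(bp_data):
    return fecvar.fit(2, bp_data, mcmc=MCMCSettings(burn_in=2000, draws=4000, seed=21))


@pytest.fixture(scope="session")
def bp_fit3(bp_data):
    return fecvar.fit(3, bp_data, mcmc=MCMCSettings(burn_in=2000, draws=4000, seed=22))
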