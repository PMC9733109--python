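import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def encounter_dyads() -> pd.DataFrame:
    from competab import datasets

    return datasets.load_encounter_dyads()


@pytest.fixture(scope="session")
def sire_counts() -> pd.DataFrame:
    from competab import datasets

    return datasets.load_sire_counts()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
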