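import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dietsim as ds

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_table() -> ds.GroupIntakeTable:
    return ds.load_baseline_intakes()


@pytest.fixture(scope="session")
def modelled_reference() -> ds.GroupIntakeTable:
    return ds.load_modelled_reference()


@pytest.fixture(scope="session")
def printed_totals() -> pd.DataFrame:
    return ds.load_printed_totals()


@pytest.fixture(scope="session")
def profiles():
    return ds.default_profiles()


@pytest.fixture(scope="session")
def demo_model() -> ds.TGModel:
    return ds.load_demo_model()


@pytest.fixture(scope="session")
def library(profiles):
    return ds.scenario_library(profiles=profiles)


@pytest.fixture(scope="session")
def small_survey() -> pd.DataFrame:
    return ds.generate_population(ds.GeneratorConfig(n=606, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
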