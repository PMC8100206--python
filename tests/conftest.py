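import numpy as np
import pandas as pd
import pytest

from gdemtools.config import PipelineConfig, SimConfig
from gdemtools.pipeline import run_on_study
from gdemtools.simulate import simulate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 17 samples, 20 planted GDEM genes."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def result(study):
    """Full pipeline result on the default study."""
    return run_on_study(study, PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """Light study for file-format and CLI tests."""
    return simulate_study(SimConfig(n_genes=12, n_gdem=4, n_discordant=1,
                                    n_gde_only=2, n_dmr_only=2,
                                    n_cpgs=800, seed=42))


@pytest.fixture()
def toy_samples():
    """Hand-built metadata with every stratification boundary present."""
    return pd.DataFrame({
        "sample_id": [f"P{i}" for i in range(1, 11)],
        "sjc66": [12, 9, 20, 9, 15, 8, 3, 1, 8, 0],
        "sex": ["male", "male", "female", "male", "male",
                "female", "female", "male", "female", "female"],
        "age": [55.0, 47.0, 63.0, 39.0, 51.0, 44.0, 58.0, 36.0, 61.0, 50.0],
        "dmard_use": [True, False, True, True, False,
                      True, False, False, True, False],
        "joint_source": ["knee"] * 10,
    })
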