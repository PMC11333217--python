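import numpy as np
import pandas as pd
import pytest

from gdmprs import default_panel
from gdmprs.simulate import GeneratorConfig, calibrate_intercept, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 2,541-subject cohort under the default generative model."""
    cfg = GeneratorConfig(n_subjects=2541, seed=11, prs_source="normal")
    intercept = calibrate_intercept(cfg)
    sim = generate_cohort(cfg, intercept=intercept)
    return sim.cohort


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_prs():
    """A 10-subject score frame with known ordering."""
    return pd.DataFrame({"raw_score": np.arange(1.0, 11.0)})
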