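import numpy as np
import pytest

from modfus.cohort import CohortConfig, simulate_cohort
from modfus.scales import load_scale_definitions


@pytest.fixture(scope="session")
def scale_defs():
    return load_scale_definitions()


@pytest.fixture(scope="session")
def ess_def(scale_defs):
    return scale_defs["ESS"]


@pytest.fixture(scope="session")
def tiny_cohort(scale_defs):
    """Small planted-signal cohort with prompts, shared across tests."""
    cfg = CohortConfig(n=24, score_effect=2.0, image_effect=0.5, seed=42)
    ds, _ = simulate_cohort(cfg, scale_defs)
    return ds.with_prompts(scale_defs, n=4, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
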