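import numpy as np
import pandas as pd
import pytest

from tmesurv.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def outcome_cohort() -> pd.DataFrame:
    """A mid-size outcomes-only cohort shared by the statistics tests."""
    cfg = GeneratorConfig(n_subjects=500, seed=424242)
    return generate_cohort(cfg, out_dir=None, write_images=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
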