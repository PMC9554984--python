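import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from svdrisk.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One complete synthetic cohort at the emulated study conditions."""
    return generate_cohort(GeneratorConfig(n_subjects=630, seed=7))


@pytest.fixture(scope="session")
def big_cohort() -> pd.DataFrame:
    """Large cohort for marginal-calibration checks."""
    return generate_cohort(GeneratorConfig(n_subjects=6000, seed=19))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
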