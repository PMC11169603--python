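import numpy as np
import pytest

from exposcore import default_calibration
from exposcore.pipeline import analysis_table

GXE_COVARIATES = ("age", "sex", "education") + tuple(f"pc{i + 1}" for i in range(10))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration analysis table at a modest n for structural and
    smoke tests (prevalence-level checks use their own larger draws)."""
    return analysis_table(default_calibration(4000), seed=11)
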