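import warnings

import numpy as np
import pytest

from podosim import SectionPlan, build_cohort, section_cohort
from podosim.scenarios import fafa_arm
from podosim.stereology import default_correction_model


@pytest.fixture(scope="session")
def correction_model():
    """Shared thickness/shape correction calibrated for 1.5-um sections."""
    return default_correction_model(1.5)


@pytest.fixture(scope="session")
def fafa_cohort():
    """One packaged fa/fa cohort with its section profiles (all four weeks)."""
    cohort = build_cohort(fafa_arm(), seed=314)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = section_cohort(cohort, SectionPlan(profiles_per_animal=40), seed=315)
    return cohort, profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
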