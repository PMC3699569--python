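import warnings

import numpy as np
import pytest

from inflammode import young_default
from inflammode.model import DoseProtocol, resting_state, simulate
from inflammode.synthetic import (
    MIDDLE_AGED_BEST_OVERLAY,
    default_two_arm_design,
    generate_timecourse,
)

# the LSODA wrapper warns (rather than raises) on excess work; the package
# converts those into structured errors, so the warning itself is noise
warnings.filterwarnings("ignore", message=".*Excess work.*")


@pytest.fixture(scope="session")
def young():
    return young_default()


@pytest.fixture(scope="session")
def young_rest(young):
    return resting_state(young)


@pytest.fixture(scope="session")
def young_dense_sim(young, young_rest):
    """Dense 24 h LPS trajectory at the shipped baseline."""
    return simulate(
        young, DoseProtocol(dose=1.0), init=young_rest,
        obs_times=np.arange(0.0, 1441.0, 2.0),
    )


@pytest.fixture(scope="session")
def small_dataset(young):
    """Two-age synthetic study (LPS + saline arms), default design."""
    design = default_two_arm_design(
        young, overlay=MIDDLE_AGED_BEST_OVERLAY, seed=42, noise_cv=0.2
    )
    return generate_timecourse(design)
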