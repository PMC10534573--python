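import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chromdoe as cd
from chromdoe import datasets

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def factors():
    return datasets.bbd_factors()


@pytest.fixture(scope="session")
def bbd_study():
    return datasets.load_bbd_study()


@pytest.fixture(scope="session")
def fitted(bbd_study):
    return cd.fit_all_models(bbd_study, datasets.DEFAULT_MODEL_TERMS)


@pytest.fixture(scope="session")
def table3_ref():
    return datasets.table3_reference()


@pytest.fixture(scope="session")
def pb_study():
    return datasets.load_pb_study()


@pytest.fixture(scope="session")
def pb_results(pb_study):
    return cd.PlackettBurmanModel(pb_study).fit()


@pytest.fixture(scope="session")
def design_space(fitted, factors):
    return cd.DesignSpace(fitted, factors)


@pytest.fixture(scope="session")
def full_grid():
    return cd.GridSpec(
        {
            "methanol_initial": (35.0, 0.25, 40.0),
            "methanol_final": (75.0, 0.5, 85.0),
            "gradient_duration": (15.0, 0.5, 20.0),
        }
    )


@pytest.fixture(scope="session")
def small_grid():
    # 5 x 5 x 3 subgrid of the study region, for cheap Monte Carlo checks
    return cd.GridSpec(
        {
            "methanol_initial": (35.0, 1.25, 40.0),
            "methanol_final": (75.0, 2.5, 85.0),
            "gradient_duration": (15.0, 2.5, 20.0),
        }
    )


#: Natural coordinates of the verified working point and its coded image.
WORKING_POINT = (38.5, 77.5, 16.25)
WORKING_POINT_CODED = np.array([0.4, -0.5, -0.5])
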