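import numpy as np
import pytest

import octaflow as of


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_image():
    """A lesion-free synthetic SVP angiogram with its ground truth."""
    return of.generate_vessel_image(of.ImageSimConfig(seed=7))


@pytest.fixture(scope="session")
def lesion_image():
    """A synthetic SVP angiogram with one 0.25-mm² parafoveal lesion."""
    cfg = of.ImageSimConfig(seed=7, lesions=(of.lesion_spec_for_area(0.25),))
    return of.generate_vessel_image(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    return of.generate_cohort(of.CohortSimConfig(seed=11))
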