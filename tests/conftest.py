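import numpy as np
import pytest

from shuntflow.constitutive import OgdenParams
from shuntflow.synthetic_data import (
    MR5_GRAFT_1,
    OGDEN_AORTA,
    YEOH_GRAFT_1,
    YEOH_GRAFT_2,
    hgo_aorta_matched,
)


@pytest.fixture(scope="session")
def all_hyperelastic_models():
    """One representative parameter set per hyperelastic family."""
    return {
        "yeoh3": YEOH_GRAFT_1,
        "mooney_rivlin5": MR5_GRAFT_1,
        "ogden": OGDEN_AORTA,
        "hgo": hgo_aorta_matched(),
    }


@pytest.fixture(scope="session")
def neo_hookean():
    return OgdenParams(terms=((0.5, 2.0),))


@pytest.fixture(scope="session")
def stretch_grid():
    """Uniaxial stretch window excluding the stress-free reference point,
    where a relative error against P = 0 is undefined (P(1) = 0 is asserted
    exactly in its own tests)."""
    grid = np.linspace(0.5, 2.5, 400)
    assert not np.any(np.isclose(grid, 1.0, atol=1e-9))
    return grid


@pytest.fixture(scope="session")
def graft_models():
    return {"yeoh1": YEOH_GRAFT_1, "yeoh2": YEOH_GRAFT_2, "mr5_1": MR5_GRAFT_1}
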