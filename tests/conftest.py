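import numpy as np
import pytest

from soilscape.geostat import VariogramModel
from soilscape.synthetic import LandscapeSpec, make_design


@pytest.fixture(scope="session")
def study_sites():
    """The 278-site design: 248-node 215 m grid plus 30 short-range infill."""
    frame = make_design(LandscapeSpec(seed=42))
    return frame[["x", "y"]].to_numpy()


@pytest.fixture(scope="session")
def exp_model():
    """Exponential (Matérn ν=0.5) model with a 599 m effective range."""
    return VariogramModel("matern", nugget=0.1, psill=0.9, phi=200.0, nu=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
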