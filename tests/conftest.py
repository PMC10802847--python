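import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fracture3d import FractureSpec, PhantomSpec, generate


@pytest.fixture(scope="session")
def fractured_phantom():
    """128x128x16 tube with one 57-degree cortical gap on slices 5-9."""
    spec = PhantomSpec(
        rows=128,
        cols=128,
        n_slices=16,
        radius_outer=36,
        radius_inner=26,
        fractures=(FractureSpec(5, 10, angle_center=0.7, angle_width=1.0),),
    )
    return generate(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Same tube with no fracture."""
    spec = PhantomSpec(rows=128, cols=128, n_slices=8, radius_outer=36, radius_inner=26)
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
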