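import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from monofil import MaterialProperties, MonofilamentGeometry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# The four bench-measured devices whose geometry, measured clamped-pinned
# critical force (gf) and published modulus / recomputed sliding force are
# used as worked-example fixtures throughout.
BENCH_DEVICES = [
    # (d_mm, L_mm, fc_gf@k=0.7, E_gpa_printed, fc_gf@k=2.0_printed)
    (0.61, 38.0, 28.91, 2.99, 3.54),
    (0.46, 41.0, 9.80, 3.65, 1.20),
    (0.71, 38.0, 29.81, 1.68, 3.65),
    (0.52, 38.0, 13.50, 2.65, 1.65),
]


@pytest.fixture
def bench_devices():
    return BENCH_DEVICES


@pytest.fixture
def reference_10gf():
    """The longest/thinnest 10 gf device: d=0.46 mm, L=41 mm, E=3.65 GPa."""
    geometry = MonofilamentGeometry.from_mm(0.46, 41.0)
    material = MaterialProperties.from_gpa(3.65)
    return geometry, material


@pytest.fixture
def rng():
    return np.random.default_rng(20240886)
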