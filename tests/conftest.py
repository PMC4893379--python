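import numpy as np
import pytest

import cathkin as ck
from cathkin.segmentation import binarize, distance_image


@pytest.fixture(scope="session")
def arch_geometry():
    return ck.default_arch_geometry()


@pytest.fixture(scope="session")
def arch_phantom(arch_geometry):
    """Noise-free default phantom with its ground-truth mask."""
    return ck.make_phantom(arch_geometry)


@pytest.fixture(scope="session")
def arch_distance(arch_phantom):
    """Distance image of the segmented default phantom."""
    phantom, _ = arch_phantom
    return distance_image(binarize(phantom, "auto"))


@pytest.fixture(scope="session")
def straight_geometry():
    return ck.straight_tube_geometry(length=300.0, radius=12.0, start=(40.0, 60.0))


@pytest.fixture(scope="session")
def default_cohort(arch_geometry):
    """One default 6+6 cohort."""
    return ck.simulate_cohort(seed=11, geometry=arch_geometry)


@pytest.fixture(scope="session")
def default_features(default_cohort, arch_distance):
    return ck.features_table(default_cohort, arch_distance)


def minimum_jerk_trajectory(amplitude=2.5, duration=1.3, dt=1e-3, origin=(100.0, 50.0)):
    """Analytic single minimum-jerk movement along x.

    The duration is snapped to a whole number of ``dt`` steps so the last
    sample lands exactly on the movement end.
    """
    n = max(2, int(round(duration / dt))) + 1
    t = np.arange(n) * dt
    tau = t / t[-1]
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    xy = np.column_stack(
        [origin[0] + amplitude * s, np.full_like(t, origin[1])]
    )
    return ck.Trajectory(t, xy)
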