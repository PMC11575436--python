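import numpy as np
import pytest

from memstep.familiarity import GridSpec
from memstep.movement_kernel import KernelParams
from memstep.trajectory import Location, Track


@pytest.fixture
def simple_track():
    """Ten hourly fixes along a gentle arc."""
    locs = [
        Location(t=i / 24.0, x=100.0 * i + 3.0 * i * i, y=50.0 * i - 2.0 * i * i)
        for i in range(10)
    ]
    return Track(id="a1", locations=locs)


@pytest.fixture
def unit_grid():
    """20x20 grid of 10 m cells with origin at (0, 0)."""
    return GridSpec(x0=0.0, y0=0.0, res=10.0, n_rows=20, n_cols=20)


@pytest.fixture
def kernel():
    return KernelParams(gamma_shape=2.0, gamma_scale=100.0, vm_kappa=1.0)


def random_walk_track(n: int, seed: int, dt: float = 1.0 / 24.0, step: float = 50.0) -> Track:
    """Unstructured random-walk track for oracle tests."""
    rng = np.random.default_rng(seed)
    ang = np.cumsum(rng.uniform(-1.0, 1.0, size=n))
    xy = np.cumsum(
        np.column_stack([step * np.cos(ang), step * np.sin(ang)]) * rng.gamma(2.0, 1.0, size=(n, 1)),
        axis=0,
    )
    locs = [Location(t=i * dt, x=float(xy[i, 0]), y=float(xy[i, 1])) for i in range(n)]
    return Track(id=f"rw{seed}", locations=locs)
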