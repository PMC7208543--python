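import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

VOXEL = (1.5, 1.5)


@pytest.fixture(scope="session")
def voxel():
    return VOXEL


@pytest.fixture()
def rect_mask():
    """Small single-muscle mask factory."""
    from mumri import MuscleMask

    def make(grid=(24, 24), margin=2, label=1, name="TA"):
        labels = np.zeros(grid, dtype=int)
        labels[margin : grid[0] - margin, margin : grid[1] - margin] = label
        return MuscleMask(labels, {label: name})

    return make


@pytest.fixture()
def single_unit_phantom(rect_mask):
    """One circular unit in a small muscle; returns (phantom, unit)."""
    from mumri import Phantom, make_territory

    def make(noise_sigma=0.03, threshold=10.0, width=0.02, grid=(24, 24), **kw):
        mask = rect_mask(grid)
        unit = make_territory(
            "circular",
            (grid[0] / 2 - 0.5, grid[1] / 2 - 0.5),
            {"radius_mm": 3.0},
            grid,
            VOXEL,
            threshold_mA=threshold,
            firing_width_mA=width,
            **kw,
        )
        return Phantom(mask, [unit], 100.0, noise_sigma, VOXEL), unit

    return make
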