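import numpy as np
import pytest

from subbandct import FanBeamGeometry, ImageGrid, Disk, Phantom


@pytest.fixture(scope="session")
def small_geometry() -> FanBeamGeometry:
    """Reduced scanner: R_fov ≈ 71 mm, fast enough for per-test reconstructions."""
    return FanBeamGeometry(
        source_isocenter_mm=600.0,
        source_detector_mm=1100.0,
        n_channels=240,
        channel_pitch_mm=1.09,
        n_views=180,
    )


@pytest.fixture(scope="session")
def small_grid(small_geometry) -> ImageGrid:
    grid = ImageGrid(n_pixels=128, pixel_mm=1.15)
    assert grid.covers_radius(small_geometry.fov_radius_mm)
    return grid


@pytest.fixture(scope="session")
def two_disk_phantom() -> Phantom:
    return Phantom(
        (Disk((0.0, 10.0), 20.0, 0.02), Disk((30.0, -20.0), 8.0, 0.03))
    )
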