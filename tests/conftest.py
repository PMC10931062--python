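import numpy as np
import pytest
from hypothesis import settings

from octscan import ScanGeometry

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: Small grid with the same 6×6 mm FOV and 3472 µm depth extent as the
#: default Spectralis-like geometry; keeps unit tests fast.
SMALL_GEOMETRY = ScanGeometry(
    fov_x_um=6000.0,
    fov_y_um=6000.0,
    isd_um=500.0,
    n_bscans=13,
    n_ascans=96,
    n_depth=64,
    depth_scale_um=54.25,
)


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    return SMALL_GEOMETRY


def make_volume(geometry, voxels=(), eye_id="eye", laterality="right", disease="unknown"):
    """Build a retina-free volume with the given (bscan, depth, ascan, label) voxels."""
    from octscan import SegVolume

    labels = np.zeros(geometry.shape, dtype=np.uint8)
    for b, d, a, code in voxels:
        labels[b, d, a] = code
    return SegVolume(
        labels=labels,
        geometry=geometry,
        eye_id=eye_id,
        laterality=laterality,
        disease=disease,
    )
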