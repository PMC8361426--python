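import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def box_phantom():
    """Noiseless cord phantom with one 5-slice, 40% box compression."""
    from cordbold import synth

    spec = synth.CordPhantomSpec(
        n_slices=40,
        compressions=(
            synth.CompressionSpec(center_slice=20, extent_slices=5, max_area_reduction=0.4),
        ),
    )
    mask, truth = synth.make_cord_phantom(spec)
    return spec, mask, truth


@pytest.fixture(scope="session")
def noiseless_bold():
    """Noiseless 330-volume run with 2% signal in one ROI."""
    from cordbold import synth

    roi = np.zeros((8, 8, 4), dtype=bool)
    roi[2:5, 2:5, 1:3] = True
    spec = synth.BoldPhantomSpec(
        volume_shape=(8, 8, 4),
        active_rois=((roi, 2.0),),
        noise_sd=0.0,
        motion_amplitude=0.0,
    )
    return synth.make_bold_phantom(spec), roi
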