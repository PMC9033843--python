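import numpy as np
import pytest

from reactoscope.cells import CellTruth, GeneExpressionParams
from reactoscope.microscope import VirtualSampleParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_params():
    """Rendering parameters with all noise sources off."""
    return VirtualSampleParams(image_shape=(128, 128), background_level=100.0,
                               read_noise_sd=0.0, shot_noise=False,
                               bleed_psf_sigma=2.0, intensity_gain=0.01)


@pytest.fixture
def expr_params():
    return GeneExpressionParams(k=2.0, b0=0.1, gamma=0.02, tau=36.0,
                                alpha=1.0, sigma_meas=2.0)


def make_cell(cid=0, centroid=(64.0, 64.0), semi=(8.0, 6.0), **kw):
    return CellTruth(id=cid, centroid=centroid, semi_axes=semi, **kw)


@pytest.fixture
def cell_factory():
    return make_cell
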