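import warnings

import numpy as np
import pytest

from wellquant import SyntheticWellSpec, render_microwell_image


@pytest.fixture(autouse=True)
def _quiet_roi_warnings():
    # ROI-clipping and constant-input warnings are informational in tests
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def small_well_spec(**overrides):
    """A fast-rendering 150 µm well used across tests: no control ring,
    noise-free, clearly separated nuclei."""
    defaults = dict(well_diameter=150.0, seed=0, noise_sd=0.0,
                    include_control=False, min_separation=1.2)
    defaults.update(overrides)
    return SyntheticWellSpec(**defaults)


@pytest.fixture
def small_well():
    spec = small_well_spec()
    img, truth = render_microwell_image(spec)
    return spec, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
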