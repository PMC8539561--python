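import numpy as np
import pytest

import cellmap as cm


@pytest.fixture(scope="session")
def registry():
    return cm.default_registry()


@pytest.fixture
def small_axis():
    """Short axis (490-900 cm^-1, 1 cm^-1) covering noise + low bands."""
    return cm.SpectralAxis(np.arange(490.0, 901.0))


@pytest.fixture(scope="session")
def default_phantom_run(registry):
    """Default 64x64 phantom, fixed seed, processed end to end.

    Session-scoped: the baseline stage dominates suite runtime and the
    result is reused by the recovery, exclusivity and acceptance tests.
    """
    params = cm.PhantomParams()
    ph = cm.generate_phantom(params, seed=1)
    sub = cm.subtract_baseline_image(ph.image, cm.BaselineRecipe())
    noise = registry.noise_band
    maps = {
        name: cm.compute_map(sub, registry.imaging(name), noise)
        for name in ("DNA", "heme", "RNA", "protein")
    }
    return ph, sub, maps
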