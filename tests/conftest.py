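import numpy as np
import pytest

import vesselkit as vk


@pytest.fixture()
def bar3():
    """Clean horizontal bar, radius 3, on a 65x65 canvas, with its spec."""
    spec = vk.VesselPhantomSpec(radius=3.0)
    return spec, vk.make_bar_phantom(spec, 65, 65)


@pytest.fixture()
def ring100():
    """Clean quantized 100x100 ring (tube radius 2) with its truth mask."""
    center = (49.5, 49.5)
    img = vk.make_ring_phantom(center, 30.0, 2.0, 150.0, 220.0, 100, quantize=True)
    truth = vk.ring_tube_mask(center, 30.0, 2.0, 100).astype(np.uint8)
    return img, truth


@pytest.fixture()
def rough_image():
    """Seeded rough random image for conservation/stability properties."""
    return np.random.default_rng(0).uniform(0.0, 255.0, (32, 32))
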