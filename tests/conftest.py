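import numpy as np
import pytest

from carpelkit.segmentation import CarpelSegmenter
from carpelkit.synthetic import generate_scene_batch


@pytest.fixture(scope="session")
def small_scenes():
    """16 varied 64x64 scenes with ground-truth masks."""
    return generate_scene_batch(16, seed=42, image_size=(64, 64))


@pytest.fixture(scope="session")
def tiny_stigma_net(small_scenes):
    """A quickly trained 1-channel stigma segmenter on 64x64 scenes.

    Small on purpose: enough training for sanity orderings (better than
    chance, deterministic inference), not for benchmark-level accuracy.
    """
    images, stigmas, _, _ = small_scenes
    est = CarpelSegmenter(input_size=64, depth=3, base_channels=16,
                          n_output_channels=1, epochs=10, batch_size=2, seed=0)
    est.fit(images[:12], [(m,) for m in stigmas[:12]])
    return est


@pytest.fixture()
def disc_mask():
    rr, cc = np.mgrid[0:100, 0:100]
    return (rr - 50) ** 2 + (cc - 50) ** 2 <= 30 ** 2
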