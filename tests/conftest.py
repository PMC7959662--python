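import numpy as np
import pytest

from cascadix.backbones import build_network, extract_features
from cascadix.synthetic import SyntheticSpec, generate_image_dataset


@pytest.fixture(scope="session")
def small_images():
    """4 classes x 12 images, 32 px frames: the fast shared image fixture."""
    spec = SyntheticSpec(n_classes=4, n_per_class=12, image_size=(32, 32), seed=11)
    return generate_image_dataset(spec)


@pytest.fixture(scope="session")
def small_features(small_images):
    """tinycnn tap features of the small fixture (48 x 32)."""
    spec, net = build_network("tinycnn", n_classes=4, seed=2, input_hw=(32, 32))
    return extract_features(small_images, spec, network=net)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
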