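import numpy as np
import pytest

from ehfrnet import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small layout-signal corpus: 3 classes x 6 images at 32 px."""
    root = tmp_path_factory.mktemp("data") / "tiny"
    spec = SyntheticSpec(image_size=32, num_classes=3, samples_per_class=6,
                         jitter=1.0, noise_sigma=0.02, seed=7)
    generate_dataset(spec, root)
    return root, spec
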