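import numpy as np
import pytest

from meningiodet import BrainImage, PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return BrainImage(rng.integers(0, 256, size=(17, 17), dtype=np.uint8).astype(np.uint8))


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small balanced phantom dataset shared by the slower pipeline tests."""
    out = tmp_path_factory.mktemp("phantoms")
    manifest = generate_dataset(8, PhantomSpec(seed=99, size=96, tumor_radius=(6, 14)), str(out))
    return manifest, str(out)
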