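import numpy as np
import pytest

from histopatch.model import ModelConfig, build_model
from histopatch.synthetic_slide import SlideSpec, generate_slide

MICRO_CONFIG = ModelConfig(
    n_inception_a=0, n_inception_b=0, n_inception_c=0, width_multiplier=0.05
)

TINY_CONFIG = ModelConfig(
    n_inception_a=1, n_inception_b=1, n_inception_c=1, width_multiplier=0.125
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def micro_model():
    """Smallest instantiable network (no Inception repeats), random weights."""
    return build_model(MICRO_CONFIG, seed=11)


@pytest.fixture(scope="session")
def interface_slide():
    """One generated interface slide + mask at working resolution."""
    spec = SlideSpec(320, 320, "interface", cancer_fraction=0.5, seed=21)
    return generate_slide(spec)


@pytest.fixture()
def asym_patch():
    """A 101x101 RGB patch with no dihedral symmetry."""
    g = np.random.default_rng(5).random((101, 101, 3)).astype(np.float32)
    g[:10, :, 0] = 1.0  # break every rotation/reflection symmetry
    g[:, :5, 1] = 0.0
    return g
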