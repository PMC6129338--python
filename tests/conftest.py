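import numpy as np
import pytest

from dermatex import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def psoriasis_image():
    """One default psoriasis image (disk lesion r=40) with ground truth."""
    spec = synth.SynthSpec(class_label="psoriasis", seed=42,
                           noise_fraction=0.02, orientation_deg=10.0)
    return synth.generate_image(spec)


@pytest.fixture(scope="session")
def normal_image():
    spec = synth.SynthSpec(class_label="normal", seed=42,
                           noise_fraction=0.02, orientation_deg=10.0)
    return synth.generate_image(spec)
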