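import numpy as np
import pytest

from ndlesion.synthgen import PhantomConfig, render_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def easy_phantom():
    """One default (easy) phantom with its exact ground truth."""
    return render_phantom(PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and blur-free phantom: exactly two colors."""
    return render_phantom(
        PhantomConfig(seed=7, noise_sigma=0.0, fuzziness=0.0, irregularity=0.2)
    )
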