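import numpy as np
import pytest

from crackct.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom shared by read-only tests (seed 42)."""
    spec = PhantomSpec(rng_seed=42)
    grey, truth = generate_phantom(spec)
    return spec, grey, truth


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Noise-free phantom for threshold-oracle accuracy checks."""
    spec = PhantomSpec(rng_seed=43, noise_sd=0.0)
    grey, truth = generate_phantom(spec)
    return spec, grey, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
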