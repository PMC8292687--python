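import numpy as np
import pytest

from ctslice import PhantomImage, SynthParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom() -> PhantomImage:
    """One default synthetic phantom frame (5 mm nominal, seed 42)."""
    return generate_phantom(SynthParams(seed=42))


@pytest.fixture
def clean_params() -> SynthParams:
    """Noise-free, default geometry; handy for exact-geometry assertions."""
    return SynthParams(noise_sigma_hu=0.0, seed=0)


@pytest.fixture
def water_image() -> PhantomImage:
    """Uniform water with realistic noise and no stair objects."""
    rng = np.random.default_rng(7)
    return PhantomImage(
        rng.normal(0.0, 10.0, (256, 256)), (0.5078125, 0.5078125), "water"
    )
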