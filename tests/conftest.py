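import numpy as np
import pytest

from mfbiomass import BiomassField, CascadeSpec, generate_cascade

#: skewed quadrant weights used across the suite
SKEW = (0.4, 0.3, 0.2, 0.1)
STEEP = (0.55, 0.25, 0.15, 0.05)
UNIFORM = (0.25, 0.25, 0.25, 0.25)


@pytest.fixture(scope="session")
def skew_cascade_l8():
    """Microcanonical cascade, skewed weights, 256x256 (session-cached)."""
    return generate_cascade(CascadeSpec(SKEW, levels=8, mode="microcanonical", seed=42))


@pytest.fixture(scope="session")
def det_cascade_l6():
    return generate_cascade(CascadeSpec(SKEW, levels=6, mode="deterministic"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def iid_field(rng):
    return BiomassField(rng.uniform(0.5, 1.5, (128, 128)))
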