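import numpy as np
import pytest

from brainctl import synth


@pytest.fixture(scope="session")
def small_cohort():
    """15-subject paired cohort at reduced size for fast pipeline tests."""
    spec = synth.SynthCohortSpec(
        n_subjects=6, n_regions=60, frames_per_scan=120, seed=42,
        drug_amplitude_factor=0.7,
    )
    return synth.gen_two_condition_cohort(spec)


@pytest.fixture(scope="session")
def small_connectome():
    return synth.gen_connectome(60, n_modules=4, density=0.3, seed=7)


@pytest.fixture(scope="session")
def coords200():
    return synth.gen_parcel_coords(200, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
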