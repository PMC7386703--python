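import warnings

import pytest

from ovilog import synth


@pytest.fixture(scope="session")
def cohort():
    """One deterministic default-condition cohort shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.gen_cohort(synth.CohortConfig(seed=1))


@pytest.fixture
def clean_ecg_config():
    return synth.EcgSynthConfig(hr_bpm=100.0, noise_sd_uv=0.0, rr_jitter_cv=0.0, seed=1)
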