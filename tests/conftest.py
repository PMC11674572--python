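import numpy as np
import pytest

from connectodyn import SyntheticConfig, fit_hmm, gen_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Single-band cohort with well-separated states, shared across tests."""
    cfg = SyntheticConfig(
        n_subjects=12, n_regions=6, K=3, T=800,
        bands=(("alpha", 8.0, 12.0),), separation=4.0,
        planted_mode_r=0.3, seed=42,
    )
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Group HMM fit on the shared cohort (params, per-subject decodes)."""
    return fit_hmm(small_cohort.envelopes["alpha"], 3, n_restarts=2, seed=7)
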