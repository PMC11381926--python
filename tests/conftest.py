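import numpy as np
import pytest

from usprf import SessionConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One small single-PRF session with ground truth, shared across tests."""
    cfg = SessionConfig(
        protocol="single_prf", prf_set=(140.0,), n_trials_or_blocks=10,
        post_s=19.0, n_neurons=8, frac_modulated=0.25, p_evoked=0.8, seed=11,
    )
    return cfg, *generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
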