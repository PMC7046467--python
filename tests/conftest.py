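import warnings

import numpy as np
import pytest

from thetatravel.sim import SimConfig, simulate_session

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def synchronized_session():
    """Short noiseless synchronized session with the default asymmetry
    gradient (shared across tests; treat as read-only)."""
    cfg = SimConfig(mechanism="synchronized", duration_s=60.0,
                    noise_amp_uV=0.0, freq_jitter=0.0, seed=11)
    recording, truth = simulate_session(cfg)
    return cfg, recording, truth


@pytest.fixture(scope="session")
def coupled_session():
    """Coupled-mechanism session, flat asymmetry, default noise."""
    cfg = SimConfig(mechanism="coupled", duration_s=120.0, seed=21,
                    asym_rd_dorsal=0.0, asym_rd_ventral=0.0,
                    asym_pt_dorsal=0.0, asym_pt_ventral=0.0)
    recording, truth = simulate_session(cfg)
    return cfg, recording, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
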