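import numpy as np
import pytest

from cvepkit import codes, synth


@pytest.fixture(scope="session")
def bank() -> codes.CodeBank:
    return codes.build_code_bank()


@pytest.fixture(scope="session")
def small_epochs(bank) -> synth.EpochSet:
    """2 sessions x 30 trials at high SNR — quick, easily decodable."""
    cfg = synth.SimConfig(
        n_sessions=2, n_trials_per_session=30, snr_db=30,
        jitter_samples=0, seed=7,
    )
    return synth.simulate_epochs(cfg, bank)


@pytest.fixture(scope="session")
def tiny_epochs(bank) -> synth.EpochSet:
    """1 session x 18 trials at very high SNR for network smoke tests."""
    cfg = synth.SimConfig(
        n_sessions=1, n_trials_per_session=18, snr_db=40,
        jitter_samples=0, seed=3,
    )
    return synth.simulate_epochs(cfg, bank)
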