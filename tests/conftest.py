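import numpy as np
import pytest

from burstsync.synth import (
    CHANNEL_ROLES,
    Recording,
    fast_coupling_spec,
    fast_task_config,
    generate_participant,
)


@pytest.fixture(scope="session")
def fast_cfg():
    return fast_task_config()


@pytest.fixture(scope="session")
def fast_spec():
    return fast_coupling_spec()


@pytest.fixture(scope="session")
def participant(fast_cfg, fast_spec):
    """One default fast-preset participant: (schedule, recordings, ground truth)."""
    return generate_participant(fast_cfg, fast_spec, seed=11)


@pytest.fixture(scope="session")
def clean_coupled_participant(fast_cfg):
    """Low-noise, narrow-linewidth participant with strong F0 burst coupling;
    used for phase-level parameter-recovery checks."""
    spec = fast_coupling_spec(
        kappa_burst={"F0": 8.0, "F1": 0.0, "F2": 0.0},
        emg_noise_amp=0.02,
        pink_amp=0.05,
        beta_am_sigma=0.0,
        gamma_amp=0.0,
        beta_linewidth_hz=0.5,
    )
    return generate_participant(fast_cfg, spec, seed=3)


def make_recording(x: np.ndarray, fs: float = 512.0) -> Recording:
    """Wrap a single trace into a 5-channel Recording (same trace per channel)."""
    return Recording(
        data=np.vstack([x] * len(CHANNEL_ROLES)),
        fs=fs,
        roles=CHANNEL_ROLES,
        events=None,
        block=0,
    )
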