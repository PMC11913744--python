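import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from intersectinfo.preprocess import align_trials, compute_dff
from intersectinfo.synthetic import SessionConfig, generate_session

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stage3_session():
    """A small expert-stage session: strong tuning and choice coupling."""
    cfg = SessionConfig(n_neurons=16, n_trials=120, performance=0.85,
                        stim_gain=0.10, choice_gain=0.10, seed=42)
    trials, fluor, truth = generate_session(cfg)
    return cfg, trials, fluor, truth


@pytest.fixture(scope="session")
def stage3_tensor(stage3_session):
    """Trial-aligned ΔF/F0 tensor plus labels for the expert-stage session."""
    cfg, trials, fluor, truth = stage3_session
    dff = compute_dff(fluor)
    tensor = align_trials(dff, trials, (-3.0, 7.0), cfg.frame_rate)
    inc = tensor.included_trials
    return {
        "config": cfg,
        "trials": trials,
        "truth": truth,
        "tensor": tensor,
        "stimulus": trials["stimulus"].to_numpy()[inc],
        "choice": trials["choice"].to_numpy()[inc],
    }


@pytest.fixture(scope="session")
def null_session():
    """A session with no encoded signal at all (type-I error checks)."""
    cfg = SessionConfig(n_neurons=16, n_trials=100, performance=0.7,
                        stim_gain=0.0, choice_gain=0.0, seed=99)
    trials, fluor, truth = generate_session(cfg)
    dff = compute_dff(fluor)
    tensor = align_trials(dff, trials, (0.0, 1.0), cfg.frame_rate)
    inc = tensor.included_trials
    return {
        "config": cfg,
        "trials": trials,
        "tensor": tensor,
        "stimulus": trials["stimulus"].to_numpy()[inc],
        "choice": trials["choice"].to_numpy()[inc],
    }
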