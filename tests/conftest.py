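import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_dataset():
    """One participant's scaled-down dataset with all default planted effects."""
    from prioshift.synth import SignalSpec, TaskConfig, simulate_dataset

    trials, epochs = simulate_dataset(TaskConfig(n_blocks=16), SignalSpec(), seed=11)
    return trials, epochs


@pytest.fixture(scope="session")
def noise_epochs():
    """Signal-free epochs (all amplitudes zero) with the matching trial table."""
    from prioshift.synth import SignalSpec, TaskConfig, simulate_dataset

    spec = SignalSpec(evoked_snr=0.0, theta_amp=0.0, beta_amp=0.0)
    trials, epochs = simulate_dataset(TaskConfig(n_blocks=16), spec, seed=21)
    return trials, epochs


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A minimal end-to-end pipeline run shared across tests."""
    from prioshift.pipeline import RunConfig, run_synthetic_study

    cfg = RunConfig(profile="ci", n_participants=3, n_blocks=16, n_perm=100,
                    decode_timepoints=(1.1,), score_window=(1.1, 1.1), master_seed=5)
    out = tmp_path_factory.mktemp("study") / "run"
    summary = run_synthetic_study(cfg, out)
    return cfg, out, summary
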