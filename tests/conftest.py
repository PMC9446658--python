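import numpy as np
import pytest

from mibci import preprocessing as pre
from mibci import synthetic as syn


def make_dataset(erd_depth: float, n_trials_per_run: int, seed: int) -> pre.RestructuredDataset:
    """Generate, preprocess, and pool one synthetic session."""
    ss = np.random.SeedSequence(seed)
    s_sched, s_eeg = (int(s) for s in ss.generate_state(2))
    schedules = syn.make_session_schedules(n_trials_per_run, seed=s_sched)
    rec = syn.generate_session(
        syn.SyntheticConfig(erd_depth=erd_depth), schedules, seed=s_eeg
    )
    epochs = pre.preprocess_recording(rec)
    return pre.restructure_runs([epochs])


@pytest.fixture(scope="session")
def small_strong_dataset():
    """12-trial runs (18 trials/class) with strong ERD; shared across tests."""
    return make_dataset(erd_depth=0.5, n_trials_per_run=12, seed=7)


@pytest.fixture(scope="session")
def small_null_dataset():
    """12-trial runs with no class effect (erd_depth = 0)."""
    return make_dataset(erd_depth=0.0, n_trials_per_run=12, seed=7)
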