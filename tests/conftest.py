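import numpy as np
import pytest

import erpfood as e


@pytest.fixture(scope="session")
def small_subject():
    """One simulated subject at reduced scale, raw (unprocessed)."""
    cfg = e.SimulationConfig(
        n_subjects=1, blocks=1, food_per_block=10, nonfood_per_block=6, seed=42
    )
    recording, events = e.simulate_subject(cfg, 0)
    return cfg, recording, events


@pytest.fixture(scope="session")
def small_epochs(small_subject):
    """Preprocessed epochs of the small subject (no rejection)."""
    _, recording, events = small_subject
    epochs, _ = e.preprocess_recording(recording, events, ptp_threshold_uv=None)
    return epochs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochs(data, fs=1024.0, labels=None, subjects=None, montage=None, corrected=True):
    """EpochSet around arbitrary trials × channels × time data."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_time = data.shape
    montage = montage or e.Montage(tuple(f"ch{i}" for i in range(n_ch)))
    pre = int(round(0.2 * fs))
    time_ms = (np.arange(-pre, n_time - pre) / fs) * 1000.0
    labels = labels if labels is not None else np.array(["food"] * n_trials, dtype=object)
    subjects = subjects if subjects is not None else np.array(["S01"] * n_trials, dtype=object)
    return e.EpochSet(
        data, time_ms, labels, subjects, montage, fs, baseline_corrected=corrected
    )
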