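"""Shared fixtures: synthetic recordings reused across test modules."""
import numpy as np
import pytest

import somnoflux as sf
from somnoflux.synth import default_calibration_plan


@pytest.fixture(scope="session")
def wt_config():
    return sf.default_sim_config("WT")


@pytest.fixture(scope="session")
def wt_day(wt_config):
    """A full 24-h WT recording: hypnogram, signals, features, biosensor."""
    hyp = sf.simulate_hypnogram(wt_config, 24.0, seed=1)
    eeg, emg = sf.synthesize_eeg_emg(hyp, wt_config, seed=2)
    feats = sf.compute_epoch_features(eeg, emg)
    trace = sf.synthesize_biosensor(hyp, wt_config, seed=3)
    return {"hypnogram": hyp, "eeg": eeg, "emg": emg, "features": feats,
            "trace": trace}


@pytest.fixture(scope="session")
def wt_series(wt_config, wt_day):
    """Calibrated, normalized 10-s concentration series for the WT day."""
    cal_trace, plan = sf.synthesize_calibration_trace(
        wt_config, default_calibration_plan(), seed=4)
    record = sf.calibrate(cal_trace, plan)
    series = sf.current_to_concentration(wt_day["trace"], record)
    return sf.normalize_percent_of_mean(series)


def random_hypnogram(rng, n_epochs, p_stay=0.9):
    """Unstructured random hypnogram for oracle comparisons."""
    states = np.array(["WAKE", "NREM", "REM"], dtype=object)
    labels = np.empty(n_epochs, dtype=object)
    s = rng.integers(3)
    for i in range(n_epochs):
        if rng.random() > p_stay:
            s = rng.integers(3)
        labels[i] = states[s]
    return sf.Hypnogram(labels)
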