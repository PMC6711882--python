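import numpy as np
import pandas as pd
import pytest

from mweeg import synth
from mweeg.containers import CHANNELS, EpochSet, default_time_axis


@pytest.fixture()
def time_axis():
    return default_time_axis()


@pytest.fixture()
def make_epochs(time_axis):
    """Factory for small EpochSets with caller-provided channel data."""

    def _make(n_trials=4, fill=0.0, data=None, states=None):
        if data is None:
            data = np.full((n_trials, len(CHANNELS), time_axis.size), fill,
                           dtype=np.float32)
        trials = pd.DataFrame({"trial_id": np.arange(data.shape[0])})
        if states is not None:
            trials["state"] = states
        return EpochSet(data, list(CHANNELS), 256.0, time_axis, trials)

    return _make


@pytest.fixture()
def quiet_gen():
    """Generator parameters with all stochastic nuisance terms disabled."""

    def _make(**overrides):
        base = dict(
            mw_rate=0.5, leak_prob=0.0, noise_sd=0.0, artifact_prob=0.0,
            alpha_amp={synth.ON_TASK: 0.0, synth.MIND_WANDERING: 0.0},
            theta_amp={synth.ON_TASK: 0.0, synth.MIND_WANDERING: 0.0},
            theta_coupling_kappa={},
        )
        base.update(overrides)
        return synth.GenParams(**base)

    return _make


@pytest.fixture()
def gaussian_table():
    """Synthetic two-class marker tables for classifier tests (no EEG)."""

    def _make(n=100, d=0.0, n_markers=5, seed=0, mw_frac=0.5):
        rng = np.random.default_rng(seed)
        n_mw = int(round(n * mw_frac))
        y = np.array([synth.MIND_WANDERING] * n_mw
                     + [synth.ON_TASK] * (n - n_mw))
        X = rng.standard_normal((n, n_markers))
        X[y == synth.MIND_WANDERING] += d
        cols = {f"pow_m{i}": X[:, i] for i in range(n_markers)}
        return pd.DataFrame({"trial_id": np.arange(n), "state": y, **cols})

    return _make
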