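import numpy as np
import pandas as pd
import pytest

from neuromode.containers import EpochedEEG, RawRecording, make_trial_meta


def make_epochs(
    data: np.ndarray,
    fs: float = 1000.0,
    tmin: float = -1.0,
    channel_names: list[str] | None = None,
    correct: np.ndarray | None = None,
) -> EpochedEEG:
    """Build an EpochedEEG around a raw (trials, channels, samples) array."""
    n_trials, n_ch, n_samp = data.shape
    times = tmin + np.arange(n_samp) / fs
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    if correct is None:
        correct = np.ones(n_trials, dtype=bool)
    meta = make_trial_meta(
        onset_s=np.arange(n_trials, dtype=float) * 3 + 2,
        back=np.full(n_trials, 3),
        is_target=np.ones(n_trials, dtype=bool),
        response=np.ones(n_trials, dtype=int),
        correct=correct,
        rt_s=np.full(n_trials, 0.8),
    )
    return EpochedEEG(
        data=data, times=times, sampling_rate=fs,
        channel_names=channel_names, trial_meta=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A small synthetic bundle written once per test session."""
    from neuromode.simulate import make_small_fixture

    out = tmp_path_factory.mktemp("bundle")
    return make_small_fixture(seed=7, out_dir=out)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted cohort shared by recovery-style unit tests."""
    from neuromode.simulate import SimConfig, simulate_eeg_dataset

    cfg = SimConfig(n_subjects_per_group=1, n_trials_per_class=20, seed=3)
    subjects, groups = simulate_eeg_dataset(cfg)
    return cfg, subjects, groups


def events_frame(onsets, **overrides):
    n = len(onsets)
    base = dict(
        onset_s=np.asarray(onsets, dtype=float),
        back=np.full(n, 3),
        is_target=np.ones(n, dtype=bool),
        response=np.ones(n, dtype=int),
        correct=np.ones(n, dtype=bool),
        rt_s=np.full(n, 0.7),
    )
    base.update(overrides)
    return pd.DataFrame(base)


def make_raw(samples: np.ndarray, fs: float = 1000.0) -> RawRecording:
    names = [f"ch{i}" for i in range(samples.shape[0])]
    return RawRecording(samples=samples, sampling_rate=fs, channel_names=names)
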