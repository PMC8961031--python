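"""Core in-memory containers shared across the analysis stages.

All EEG amplitudes are in microvolts (uV), all times in seconds relative to
stimulus onset, and all frequencies in Hz.  Containers are plain frozen-ish
dataclasses; operations never mutate their inputs and always return new
instances (``replace``-style copies share immutable metadata but never the
data arrays being modified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Columns every per-trial metadata table carries.
TRIAL_META_COLUMNS = ("onset_s", "back", "is_target", "response", "correct", "rt_s")


@dataclass
class RawRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in uV.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_names : list of str
        Electrode labels (10-20 montage names).
    reference_label : str
        The online reference electrode (CPz for the emulated amplifier).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    reference_label: str = "CPz"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"channel count {self.samples.shape[0]} != "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class EpochedEEG:
    """Stimulus-locked epochs: trials x channels x samples, in uV.

    ``times`` is the epoch time axis in seconds relative to stimulus onset
    (sample at exactly t=0 belongs to the epoch; the grid is inclusive at
    both ends).  ``trial_meta`` is a DataFrame aligned row-for-row with the
    first axis of ``data``; ``rejected_mask`` marks trials excluded from all
    downstream statistics (the data rows are physically dropped when a
    rejection operation runs, the mask records bookkeeping for the survivors'
    provenance).
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    trial_meta: pd.DataFrame
    rejected_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match times vector")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta rows do not match trial count")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "EpochedEEG":
        """Return a shallow-copied container with the given fields replaced."""
        base = dict(
            data=self.data,
            times=self.times,
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            trial_meta=self.trial_meta.reset_index(drop=True),
            rejected_mask=self.rejected_mask,
        )
        base.update(kw)
        return EpochedEEG(**base)

    def take_trials(self, idx: np.ndarray) -> "EpochedEEG":
        idx = np.asarray(idx)
        return self.copy_with(
            data=self.data[idx],
            trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True),
            rejected_mask=self.rejected_mask[idx],
        )


@dataclass
class TFDecomposition:
    """Single-trial time-frequency power.

    ``power`` has shape (trials, channels, freqs, times) and is in uV^2 for
    ``scale_tag='absolute'`` or dB relative to a pre-stimulus baseline for
    ``scale_tag='dB-vs-baseline'``.  Time points where the analysis wavelet
    support extends past the epoch are NaN (masked, never zero-filled).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    cycles_scheme: tuple[float, float]
    padratio: int
    window_len_ms: float
    scale_tag: str = "absolute"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.padratio < 1 or (self.padratio & (self.padratio - 1)) != 0:
            raise ValueError("padratio must be a power of two")


@dataclass
class PowerFeature:
    """Per-trial, per-channel scalar power features.

    ``values`` has shape (trials, channels).  ``band_or_freq`` is either a
    single frequency in Hz or an (low, high) interval; ``time_window`` is the
    averaging window in seconds.
    """

    values: np.ndarray
    band_or_freq: float | tuple[float, float]
    time_window: tuple[float, float]
    channel_names: list[str]
    scale_tag: str = "absolute"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def make_trial_meta(
    onset_s: Sequence[float],
    back: Sequence[int],
    is_target: Sequence[bool],
    response: Sequence[int],
    correct: Sequence[bool],
    rt_s: Sequence[float],
) -> pd.DataFrame:
    """Assemble a trial metadata table with the canonical column set."""
    return pd.DataFrame(
        {
            "onset_s": np.asarray(onset_s, dtype=float),
            "back": np.asarray(back, dtype=int),
            "is_target": np.asarray(is_target, dtype=bool),
            "response": np.asarray(response, dtype=int),
            "correct": np.asarray(correct, dtype=bool),
            "rt_s": np.asarray(rt_s, dtype=float),
        }
    )
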