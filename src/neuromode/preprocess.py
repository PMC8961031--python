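"""Preprocessing chain for task EEG.

The chain mirrors standard practice for stimulus-locked analyses and runs in
a fixed, logged order: band-pass filter (1-48 Hz) -> epoch (-1.0..+1.5 s) ->
baseline correction (-0.5..0 s) -> average reference -> amplitude-threshold
rejection (>100 uV from baseline) -> correct-trial selection.  Ocular-ICA
cleanup is deliberately not part of the chain; large ocular artifacts are
caught by the amplitude threshold instead, and the skipped step is logged.

No operation mutates its input; each returns a new container.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import EpochedEEG, RawRecording, make_trial_meta

logger = logging.getLogger(__name__)


def bandpass(raw: RawRecording, low: float = 1.0, high: float = 48.0) -> RawRecording:
    """Zero-phase FIR band-pass filter (Hamming window design).

    Delegates to :func:`mne.filter.filter_data`, which designs a linear-phase
    windowed-sinc FIR filter and applies it with zero phase.
    """
    import mne

    nyq = raw.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for Nyquist {nyq} Hz")
    filtered = mne.filter.filter_data(
        raw.samples,
        sfreq=raw.sampling_rate,
        l_freq=low,
        h_freq=high,
        method="fir",
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    logger.info("band-pass %.3g-%.3g Hz applied to %d channels", low, high, raw.n_channels)
    return RawRecording(
        samples=filtered,
        sampling_rate=raw.sampling_rate,
        channel_names=list(raw.channel_names),
        reference_label=raw.reference_label,
    )


def epoch(raw: RawRecording, events, window: tuple[float, float] = (-1.0, 1.5)) -> EpochedEEG:
    """Cut stimulus-locked epochs around each event onset.

    The sample grid is inclusive at both ends: at 1000 Hz the (-1.0, 1.5) s
    window yields 2501 samples, with the sample at exactly t=0 belonging to
    the epoch.  Events whose window would fall outside the recording are
    dropped with a warning.
    """
    fs = raw.sampling_rate
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    if i1 <= i0:
        raise ValueError("epoch window must have positive length")
    times = np.arange(i0, i1 + 1) / fs

    onsets = np.round(np.asarray(events["onset_s"], dtype=float) * fs).astype(int)
    n_times = raw.samples.shape[1]
    keep = (onsets + i0 >= 0) & (onsets + i1 + 1 <= n_times)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%d event(s) outside the recording were dropped", n_dropped)

    data = np.stack(
        [raw.samples[:, s + i0 : s + i1 + 1] for s in onsets[keep]]
    ) if keep.any() else np.empty((0, raw.n_channels, times.size))

    ev = events.loc[np.asarray(keep)].reset_index(drop=True)
    meta = make_trial_meta(
        ev["onset_s"], ev["back"], ev["is_target"], ev["response"], ev["correct"], ev["rt_s"]
    )
    return EpochedEEG(
        data=data,
        times=times,
        sampling_rate=fs,
        channel_names=list(raw.channel_names),
        trial_meta=meta,
    )


def baseline_correct(ep: EpochedEEG, baseline: tuple[float, float] = (-0.5, 0.0)) -> EpochedEEG:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = (ep.times >= baseline[0]) & (ep.times <= baseline[1])
    if not mask.any():
        raise ValueError(f"baseline {baseline} contains no samples of the epoch window")
    means = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return ep.copy_with(data=ep.data - means)


def reject_amplitude(ep: EpochedEEG, threshold: float = 100.0) -> EpochedEEG:
    """Drop epochs containing any |sample| > threshold uV on any channel.

    Applied after baseline correction, so the threshold is an excursion
    "from baseline".  Raises if every trial would be rejected.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = np.any(np.abs(ep.data) > threshold, axis=(1, 2))
    if bad.all():
        raise RuntimeError(
            f"all {ep.n_trials} trials exceed the {threshold} uV rejection threshold"
        )
    logger.info("amplitude rejection at %.4g uV: %d of %d trials rejected",
                threshold, int(bad.sum()), ep.n_trials)
    kept = ep.take_trials(np.flatnonzero(~bad))
    return kept


def average_reference(ep: EpochedEEG) -> EpochedEEG:
    """Re-reference to the cross-channel average (channel mean = 0 per sample)."""
    if ep.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return ep.copy_with(data=ep.data - ep.data.mean(axis=1, keepdims=True))


def select_correct_trials(ep: EpochedEEG) -> EpochedEEG:
    """Keep only correctly responded trials."""
    correct = ep.trial_meta["correct"].to_numpy(dtype=bool)
    if not correct.any():
        raise RuntimeError("no correctly responded trials remain")
    n_drop = int((~correct).sum())
    if n_drop:
        logger.info("dropping %d incorrect trial(s), %d remain", n_drop, int(correct.sum()))
    return ep.take_trials(np.flatnonzero(correct))


def preprocess_pipeline(
    raw: RawRecording,
    events,
    *,
    filter_low_hz: float = 1.0,
    filter_high_hz: float = 48.0,
    epoch_window: tuple[float, float] = (-1.0, 1.5),
    baseline: tuple[float, float] = (-0.5, 0.0),
    reject_threshold_uv: float = 100.0,
) -> EpochedEEG:
    """Run the full fixed-order preprocessing chain on one recording."""
    logger.info("preprocess order: filter -> epoch -> baseline -> "
                "(ocular ICA step skipped by design) -> average reference -> "
                "amplitude rejection -> correct-trial selection")
    out = bandpass(raw, filter_low_hz, filter_high_hz)
    ep = epoch(out, events, epoch_window)
    ep = baseline_correct(ep, baseline)
    ep = average_reference(ep)
    ep = reject_amplitude(ep, reject_threshold_uv)
    ep = select_correct_trials(ep)
    return ep
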