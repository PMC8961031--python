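"""Wavelet time-frequency decomposition, ERSP and power features.

The decomposition follows the newtimef-style parameterisation: the analysis
wavelet starts at ``cycles=(3, 0.5)`` -- 3 cycles at the lowest frequency,
with the cycle count expanding linearly with frequency so that the highest
frequency uses ``1 - 0.5 = 50%`` of the cycle count an equivalent
fixed-length FFT window would have there.  The wavelet envelope is a Hanning
taper.  Single-trial power is computed and then averaged (capturing induced
as well as evoked activity); time points whose wavelet support extends past
the epoch are masked with NaN rather than zero-filled.

The frequency grid is controlled by ``padratio``: grid spacing equals a base
spacing divided by ``padratio``, where the base spacing is the power of two
nearest (in log2) to the reciprocal analysis-window length.  For the default
350 ms window the base spacing is 4 Hz, so ``padratio=2`` gives a 2 Hz grid
and ``padratio=8`` a 0.5 Hz grid on which the integer frequencies
4, 5, 6, 7, 8 Hz are exactly representable.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import oaconvolve

from .containers import EpochedEEG, PowerFeature, TFDecomposition

DEFAULT_CYCLES = (3.0, 0.5)
DEFAULT_WINDOW_MS = 350.0
DEFAULT_POWER_WINDOW = (0.1, 0.7)
INTEGER_FREQS = (4.0, 5.0, 6.0, 7.0, 8.0)


def save_tfr(tf: TFDecomposition, path) -> None:
    """Serialise a decomposition to a portable ``.npz`` array container.

    Array fields are stored as arrays; the analysis parameters travel in an
    attribute manifest array of ``key=value`` strings.
    """
    manifest = np.array(
        [
            f"cycles_base={tf.cycles_scheme[0]}",
            f"cycles_expansion={tf.cycles_scheme[1]}",
            f"padratio={tf.padratio}",
            f"window_len_ms={tf.window_len_ms}",
            f"scale_tag={tf.scale_tag}",
        ]
    )
    np.savez_compressed(
        path,
        power=tf.power,
        freqs=tf.freqs,
        times=tf.times,
        channel_names=np.array(tf.channel_names),
        manifest=manifest,
    )


def load_tfr(path) -> TFDecomposition:
    """Load a decomposition written by :func:`save_tfr`."""
    with np.load(path, allow_pickle=False) as data:
        attrs = dict(item.split("=", 1) for item in data["manifest"])
        return TFDecomposition(
            power=data["power"],
            freqs=data["freqs"],
            times=data["times"],
            channel_names=[str(c) for c in data["channel_names"]],
            cycles_scheme=(float(attrs["cycles_base"]), float(attrs["cycles_expansion"])),
            padratio=int(attrs["padratio"]),
            window_len_ms=float(attrs["window_len_ms"]),
            scale_tag=attrs["scale_tag"],
        )


def base_spacing_hz(window_len_ms: float) -> float:
    """Base frequency-grid spacing: nearest power of two to 1/window_len."""
    recip = 1000.0 / window_len_ms
    return float(2.0 ** np.round(np.log2(recip)))


def freq_grid(freq_min: float, freq_max: float, padratio: int, window_len_ms: float = DEFAULT_WINDOW_MS) -> np.ndarray:
    """Grid of analysis frequencies: multiples of base_spacing/padratio."""
    if padratio < 1 or (padratio & (padratio - 1)) != 0:
        raise ValueError("padratio must be a power of two")
    df = base_spacing_hz(window_len_ms) / padratio
    k0 = int(np.ceil(freq_min / df - 1e-9))
    k1 = int(np.floor(freq_max / df + 1e-9))
    if k1 < k0:
        raise ValueError(f"no grid frequencies in [{freq_min}, {freq_max}] at spacing {df}")
    return df * np.arange(max(k0, 1), k1 + 1)


def cycles_at(
    freqs: np.ndarray,
    cycles: tuple[float, float] = DEFAULT_CYCLES,
    anchor: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-frequency wavelet cycle counts under the (base, expansion) scheme.

    Linear expansion from ``base`` cycles at the lowest analysis frequency up
    to ``(1 - expansion) * base * f_max/f_min`` cycles at the highest (the
    cycle count a constant-length window would imply, scaled down).  The
    schedule is anchored at the full analysis range ``anchor``; evaluating a
    subset of frequencies does not change their wavelets.
    """
    freqs = np.asarray(freqs, dtype=float)
    c0, q = cycles
    f_lo, f_hi = anchor if anchor is not None else (freqs[0], freqs[-1])
    if f_hi <= f_lo:
        return np.full(freqs.shape, c0)
    c_top = (1.0 - q) * c0 * f_hi / f_lo
    # never shrink below the base cycle count
    c_top = max(c_top, c0)
    return c0 + (freqs - f_lo) / (f_hi - f_lo) * (c_top - c0)


def _hanning_wavelet(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex wavelet: Hanning-tapered complex exponential, unit response.

    Normalised so that a unit-amplitude real sinusoid at ``freq`` yields
    power 1 (amplitude-squared scale).
    """
    n_samp = int(round(n_cycles / freq * fs))
    n_samp += (n_samp + 1) % 2  # odd length, centred
    t = (np.arange(n_samp) - n_samp // 2) / fs
    env = np.hanning(n_samp)
    w = env * np.exp(2j * np.pi * freq * t)
    w -= env * (w.sum() / env.sum())  # remove residual DC response
    return w * (2.0 / env.sum())


def morlet_decompose(
    ep: EpochedEEG,
    freqs: np.ndarray | None = None,
    cycles: tuple[float, float] = DEFAULT_CYCLES,
    padratio: int = 2,
    window_len_ms: float = DEFAULT_WINDOW_MS,
    freq_range: tuple[float, float] = (4.0, 30.0),
    channels: list[str] | None = None,
    cycles_anchor: tuple[float, float] | None = None,
) -> TFDecomposition:
    """Single-trial wavelet power, trials x channels x freqs x times.

    ``freqs`` defaults to the padratio-controlled grid over ``freq_range``.
    ``channels`` optionally restricts the decomposition to a channel subset
    (features for other channels are simply never needed downstream).
    ``cycles_anchor`` pins the cycle-expansion schedule to the full analysis
    range when only a sub-grid is evaluated.
    """
    nyq = ep.sampling_rate / 2.0
    if freqs is None:
        freqs = freq_grid(freq_range[0], freq_range[1], padratio, window_len_ms)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= nyq) or np.any(freqs <= 0):
        raise ValueError(f"frequencies must lie in (0, {nyq}) Hz")

    if channels is None:
        ch_idx = np.arange(ep.n_channels)
        ch_names = list(ep.channel_names)
    else:
        missing = [c for c in channels if c not in ep.channel_names]
        if missing:
            raise ValueError(f"unknown channels: {missing}")
        ch_idx = np.array([ep.channel_names.index(c) for c in channels])
        ch_names = list(channels)

    data = ep.data[:, ch_idx, :]
    n_trials, n_ch, n_times = data.shape
    ncyc = cycles_at(freqs, cycles, anchor=cycles_anchor)

    power = np.empty((n_trials, n_ch, freqs.size, n_times))
    flat = data.reshape(n_trials * n_ch, n_times)
    for fi, (f, c) in enumerate(zip(freqs, ncyc)):
        w = _hanning_wavelet(f, c, ep.sampling_rate)
        conv = oaconvolve(flat, w[None, :], mode="same", axes=1)
        p = np.abs(conv) ** 2
        half = w.size // 2
        if half > 0:
            p[:, :half] = np.nan
            p[:, n_times - half:] = np.nan
        power[:, :, fi, :] = p.reshape(n_trials, n_ch, n_times)

    return TFDecomposition(
        power=power,
        freqs=freqs,
        times=ep.times.copy(),
        channel_names=ch_names,
        cycles_scheme=cycles,
        padratio=padratio,
        window_len_ms=window_len_ms,
        scale_tag="absolute",
    )


def ersp(
    tf: TFDecomposition,
    baseline: tuple[float, float] = (-0.5, 0.0),
    per_trial: bool = False,
) -> TFDecomposition:
    """Baseline-relative power in dB: 10*log10(power / mean baseline power).

    The baseline mean is taken over the baseline time window and, by
    default, across trials (a common baseline per channel x frequency);
    ``per_trial=True`` divides each trial by its own baseline instead.
    """
    if tf.scale_tag != "absolute":
        raise ValueError("ersp expects absolute-scale power")
    mask = (tf.times >= baseline[0]) & (tf.times <= baseline[1])
    if not mask.any():
        raise ValueError(f"baseline {baseline} is outside the decomposition times")
    base = np.nanmean(tf.power[:, :, :, mask], axis=3, keepdims=True)
    if not per_trial:
        base = np.nanmean(base, axis=0, keepdims=True)
    if np.any(base <= 0) or np.any(~np.isfinite(base)):
        raise ValueError("baseline power is zero or undefined; cannot form dB ratio")
    db = 10.0 * np.log10(tf.power / base)
    return TFDecomposition(
        power=db,
        freqs=tf.freqs.copy(),
        times=tf.times.copy(),
        channel_names=list(tf.channel_names),
        cycles_scheme=tf.cycles_scheme,
        padratio=tf.padratio,
        window_len_ms=tf.window_len_ms,
        scale_tag="dB-vs-baseline",
    )


def mean_power(
    tf: TFDecomposition,
    band: tuple[float, float],
    window: tuple[float, float] = DEFAULT_POWER_WINDOW,
) -> PowerFeature:
    """Mean power over a frequency band and time window, per trial x channel."""
    fmask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    if not fmask.any():
        raise ValueError(f"band {band} contains no grid frequencies {tf.freqs}")
    tmask = (tf.times >= window[0]) & (tf.times <= window[1])
    if not tmask.any():
        raise ValueError(f"window {window} contains no time points")
    sub = tf.power[:, :, fmask, :][:, :, :, tmask]
    vals = np.nanmean(sub, axis=(2, 3))
    return PowerFeature(
        values=vals,
        band_or_freq=(band[0], band[1]),
        time_window=window,
        channel_names=list(tf.channel_names),
        scale_tag=tf.scale_tag,
    )


def integer_freq_power(
    tf: TFDecomposition,
    freqs: tuple[float, ...] = INTEGER_FREQS,
    window: tuple[float, float] = DEFAULT_POWER_WINDOW,
) -> dict[float, PowerFeature]:
    """Per-frequency mean power features at exact grid frequencies.

    Requires each requested frequency to be on the decomposition grid (use
    padratio=8 for the integer 4..8 Hz set); otherwise raises with a hint.
    """
    out: dict[float, PowerFeature] = {}
    tmask = (tf.times >= window[0]) & (tf.times <= window[1])
    if not tmask.any():
        raise ValueError(f"window {window} contains no time points")
    for f in freqs:
        hit = np.flatnonzero(np.isclose(tf.freqs, f, atol=1e-9))
        if hit.size == 0:
            raise ValueError(
                f"{f} Hz is not on the analysis grid (spacing "
                f"{tf.freqs[1] - tf.freqs[0] if tf.freqs.size > 1 else 'n/a'} Hz); "
                "increase padratio (8 places the integer 4..8 Hz set on the grid)"
            )
        vals = np.nanmean(tf.power[:, :, hit[0], :][:, :, tmask], axis=2)
        out[float(f)] = PowerFeature(
            values=vals,
            band_or_freq=float(f),
            time_window=window,
            channel_names=list(tf.channel_names),
            scale_tag=tf.scale_tag,
        )
    return out
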