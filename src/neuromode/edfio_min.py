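"""Minimal European Data Format (EDF) writer and an mne-backed reader.

Only the subset of EDF needed to exchange continuous multichannel EEG is
implemented on the write side: one data record per second, 16-bit samples,
per-channel physical scaling, uV units.  The header start date/time is fixed
to a constant so that identical inputs produce byte-identical files (the
synthetic datasets carry no real acquisition date).  Reading goes through
:func:`mne.io.read_raw_edf`, an independent implementation, so a write/read
round trip cross-checks this writer.
"""

from __future__ import annotations

import numpy as np

from .containers import RawRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    # shortest decimal representation that fits the fixed-width field
    for fmt in (f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(fmt) <= width:
            return _field(fmt, width)
    raise ValueError(f"cannot encode {value} in {width} bytes")


def write_edf(path, rec: RawRecording, *, patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write a :class:`RawRecording` as a 16-bit EDF file.

    The recording length must be an integer number of seconds (one EDF data
    record per second); the synthetic generator guarantees this.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_times = rec.samples.shape
    if n_times % fs != 0:
        raise ValueError("recording length must be an integer number of seconds")
    n_records = n_times // fs

    # per-channel physical range; guard against flat channels
    pmin = rec.samples.min(axis=1)
    pmax = rec.samples.max(axis=1)
    flat = pmax - pmin < 1e-6
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    # round outward to two decimals so the header strings are short and the
    # quantisation grid is reproducible
    pmin = np.floor(pmin * 100) / 100
    pmax = np.ceil(pmax * 100) / 100

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.00", 8),  # fixed date: synthetic data, deterministic bytes
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_ch), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_field(name, 16) for name in rec.channel_names),
            b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_num(pmin[i], 8) for i in range(n_ch)),
            b"".join(_num(pmax[i], 8) for i in range(n_ch)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(fs), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round(
        (rec.samples - pmin[:, None]) * scale[:, None] + _DIG_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        # record-major layout: for each second, all channels' samples
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path, reference_label: str = "CPz") -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (uV), via mne."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return RawRecording(
        samples=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        reference_label=reference_label,
    )
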