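"""Synthetic EEG + n-back behaviour with planted, parameterised structure.

The generator emulates the study conditions the analysis pipeline assumes:

* 64-channel oscillatory EEG sampled at 1000 Hz with channel-wise 1/f
  background noise,
* a stimulus-locked band-limited source planted at configurable channels and
  frequency, with a group-dependent power ratio (class 1 = higher-capacity
  subjects receive ``group_power_ratio`` times the class-0 planted power),
* n-back behavioural tables with block (practice), back (difficulty) and
  group effects, the practice effect being larger in low performers.

Every function is deterministic under a fixed seed.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochedEEG, RawRecording, make_trial_meta
from .edfio_min import write_edf

# ---------------------------------------------------------------------------
# montage


def default_channel_names() -> list[str]:
    """A 64-electrode 10-10 montage (includes Fp1, Fp2, F3, F4)."""
    names = (
        "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 "
        "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
        "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
        "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
        "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
        "P9 P7 P5 P3 P1 Pz P2 P4 P6 P8 P10 "
        "PO7 PO3 POz PO4 PO8 "
        "O1 Oz O2 Iz"
    ).split()
    assert len(names) == 64
    return names


@functools.lru_cache(maxsize=4)
def _standard_positions() -> dict:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    return montage.get_positions()["ch_pos"]


def montage_positions(channel_names: list[str]) -> np.ndarray:
    """3-D electrode positions (meters) from the standard 10-05 montage."""
    pos = _standard_positions()
    missing = [c for c in channel_names if c not in pos]
    if missing:
        raise ValueError(f"channels not in the standard montage: {missing}")
    return np.array([pos[c] for c in channel_names])


def montage_neighbors(channel_names: list[str], k: int = 4) -> dict[str, list[str]]:
    """Immediate neighbours of each electrode: its k nearest by 3-D distance."""
    xyz = montage_positions(channel_names)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1)[:, :k]
    return {
        channel_names[i]: [channel_names[j] for j in order[i]]
        for i in range(len(channel_names))
    }


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of the synthetic EEG cohort.

    ``snr`` is the planted-source RMS over the background RMS *within the
    planted band* (a +-1/3 relative bandwidth around ``planted_freq``, i.e.
    what a 3-cycle analysis wavelet resolves) at a planted channel for a
    class-0 subject; class-1 subjects receive ``group_power_ratio`` times
    the class-0 planted *power*.  The planted source is stimulus-locked: it
    switches on at stimulus onset with a 50 ms cosine ramp and stays on to
    the end of the epoch window, with a random phase per trial (induced, not
    phase-locked activity) and a lognormal per-trial amplitude jitter
    (``amp_jitter_sd`` log-units, normalised to keep the mean power exact).
    """

    n_subjects_per_group: int = 2
    n_trials_per_class: int = 50  # trials per subject
    n_channels: int = 64
    sampling_rate: float = 1000.0
    channel_names: list[str] = field(default_factory=default_channel_names)
    planted_freq: float = 8.0
    planted_channels: list[str] = field(default_factory=lambda: ["Fp1", "Fp2"])
    group_power_ratio: float = 3.0
    snr: float = 1.0
    noise_exponent: float = 1.0
    background_rms_uv: float = 10.0
    neighbor_gain: float = 0.3
    amp_jitter_sd: float = 0.0
    epoch_window: tuple[float, float] = (-1.0, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels != len(self.channel_names):
            raise ValueError("n_channels must equal len(channel_names)")
        for ch in self.planted_channels:
            if ch not in self.channel_names:
                raise ValueError(f"planted channel {ch!r} is not a montage label")
        if not 0 < self.planted_freq < self.sampling_rate / 2:
            raise ValueError("planted_freq must lie in (0, Nyquist)")
        if self.group_power_ratio < 1:
            raise ValueError("group_power_ratio must be >= 1")
        if self.n_trials_per_class < 2:
            raise ValueError("n_trials_per_class must be >= 2")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass
class BehaviorSimParams:
    """Parameters of the behavioural generator (probabilities after clamping
    lie in [0.05, 0.98] to avoid degenerate binomials)."""

    base_acc_by_back: dict[int, float] = field(
        default_factory=lambda: {3: 0.65, 4: 0.55, 5: 0.45}
    )
    block_gain: float = 0.05
    lp_extra_gain: float = 0.05
    hp_base_boost: float = 0.12
    rt_mean_s: float = 0.9
    rt_sd_s: float = 0.15
    back_rt_slope: float = 0.08
    n_targets: int = 20  # targets per sequence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_sd_s <= 0:
            raise ValueError("rt_sd_s must be positive")


ACC_CLAMP = (0.05, 0.98)

# ---------------------------------------------------------------------------
# n-back trial sequences


def make_nback_sequence(
    back: int,
    rng: np.random.Generator,
    n_targets: int = 20,
    n_nontargets: int = 40,
    p_correct: float = 0.8,
    rt_mean_s: float = 0.9,
    rt_sd_s: float = 0.15,
    iti_s: float = 3.0,
    lead_s: float = 2.0,
) -> pd.DataFrame:
    """One n-back letter sequence as a trial table.

    The first ``back`` trials carry no response requirement and are not part
    of the target/non-target count (the experiment-1 geometry is ``back`` +
    20 targets + 40 non-targets).  Responses and RTs are drawn so that
    downstream correct-trial selection has both outcomes to work with.
    """
    n_resp = n_targets + n_nontargets
    n_total = n_resp + back
    is_target = np.zeros(n_total, dtype=bool)
    target_pos = rng.choice(np.arange(back, n_total), size=n_targets, replace=False)
    is_target[target_pos] = True

    letters = np.empty(n_total, dtype="<U1")
    alphabet = np.array(list("ABCDEFGHJKLMNPQRSTUVWXYZ"))
    for i in range(n_total):
        if i >= back and is_target[i]:
            letters[i] = letters[i - back]
        else:
            forbidden = letters[i - back] if i >= back else ""
            choice = rng.choice(alphabet)
            while choice == forbidden:
                choice = rng.choice(alphabet)
            letters[i] = choice

    correct = rng.random(n_total) < p_correct
    correct[:back] = True  # no-response lead-in trials
    response = np.where(correct, is_target.astype(int), 1 - is_target.astype(int))
    rt = np.exp(rng.normal(np.log(rt_mean_s), rt_sd_s / rt_mean_s, n_total))
    onsets = lead_s + iti_s * np.arange(n_total)

    return pd.DataFrame(
        {
            "onset_s": onsets,
            "letter": letters,
            "back": back,
            "is_target": is_target,
            "response": response,
            "correct": correct,
            "rt_s": np.round(rt, 4),
        }
    )


# ---------------------------------------------------------------------------
# EEG generation


def _pink_noise(rng: np.random.Generator, n_ch: int, n_times: int, fs: float, exponent: float, rms: float) -> np.ndarray:
    """Channel-wise independent 1/f^exponent noise with the given RMS (uV)."""
    white = rng.standard_normal((n_ch, n_times))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_times, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping[None, :], n=n_times, axis=1)
    cur = shaped.std(axis=1, keepdims=True)
    return shaped / cur * rms


def _planted_burst(times: np.ndarray, freq: float, phase: float, ramp_s: float = 0.05) -> np.ndarray:
    """Unit-amplitude sinusoid gated on for t >= 0 with a cosine onset ramp."""
    sig = np.sin(2 * np.pi * freq * times + phase)
    gate = np.zeros_like(times)
    on = times >= 0
    gate[on] = 1.0
    ramp = (times >= 0) & (times < ramp_s)
    gate[ramp] = 0.5 * (1 - np.cos(np.pi * times[ramp] / ramp_s))
    return sig * gate


def simulate_raw_subject(
    cfg: SimConfig, group: int, rng: np.random.Generator
) -> tuple[RawRecording, pd.DataFrame]:
    """One subject's continuous recording plus its event table.

    The planted source is mixed into each planted channel at unit gain and
    into its immediate montage neighbours at ``cfg.neighbor_gain`` — a
    deliberately simple stand-in for volume conduction.
    """
    fs = cfg.sampling_rate
    n_trials = cfg.n_trials_per_class
    iti_s, lead_s = 3.0, 2.0
    events = make_nback_sequence(
        back=3,
        rng=rng,
        n_targets=max(1, n_trials // 3),
        n_nontargets=n_trials - max(1, n_trials // 3) - 3,
        iti_s=iti_s,
        lead_s=lead_s,
    ).iloc[:n_trials]
    events = events.reset_index(drop=True)

    duration_s = int(np.ceil(lead_s + iti_s * n_trials + 2.0))
    n_times = int(duration_s * fs)
    data = _pink_noise(
        rng, cfg.n_channels, n_times, fs, cfg.noise_exponent, cfg.background_rms_uv
    )

    if cfg.snr > 0:
        # reference the source to the background RMS inside the planted band
        # (+-1/3 relative bandwidth, the resolution of a 3-cycle wavelet)
        band = (cfg.planted_freq * (1 - 1 / 3), cfg.planted_freq * (1 + 1 / 3))
        idx_planted = [cfg.channel_names.index(c) for c in cfg.planted_channels]
        spec = np.fft.rfft(data[idx_planted], axis=1)
        fax = np.fft.rfftfreq(n_times, d=1.0 / fs)
        in_band = (fax >= band[0]) & (fax <= band[1])
        band_power = (np.abs(spec[:, in_band]) ** 2).sum(axis=1) / (
            n_times * n_times / 2.0
        )  # one-sided Parseval: mean-square amplitude in band
        band_rms = float(np.sqrt(band_power.mean()))
        amp0 = np.sqrt(2.0) * cfg.snr * band_rms
        amp = amp0 * (np.sqrt(cfg.group_power_ratio) if group == 1 else 1.0)
        neighbors = montage_neighbors(cfg.channel_names)
        gain = np.zeros(cfg.n_channels)
        idx = {c: i for i, c in enumerate(cfg.channel_names)}
        for ch in cfg.planted_channels:
            gain[idx[ch]] = 1.0
        for ch in cfg.planted_channels:
            for nb in neighbors[ch]:
                if gain[idx[nb]] == 0.0:
                    gain[idx[nb]] = cfg.neighbor_gain

        t_rel = np.arange(
            int(round(cfg.epoch_window[0] * fs)),
            int(round(cfg.epoch_window[1] * fs)) + 1,
        ) / fs
        sd = cfg.amp_jitter_sd
        for onset in events["onset_s"].to_numpy():
            phase = rng.uniform(0, 2 * np.pi)
            # lognormal amplitude jitter, normalised so E[amp_t^2] = amp^2
            amp_t = amp * np.exp(sd * rng.standard_normal() - sd**2)
            burst = amp_t * _planted_burst(t_rel, cfg.planted_freq, phase)
            start = int(round(onset * fs)) + int(round(cfg.epoch_window[0] * fs))
            data[:, start : start + t_rel.size] += gain[:, None] * burst[None, :]

    rec = RawRecording(
        samples=data, sampling_rate=fs, channel_names=list(cfg.channel_names)
    )
    return rec, events


def _epoch_direct(rec: RawRecording, events: pd.DataFrame, window: tuple[float, float]) -> EpochedEEG:
    """Epoch a recording by direct slicing (generator-side, no filtering)."""
    fs = rec.sampling_rate
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    times = np.arange(i0, i1 + 1) / fs
    onsets = np.round(events["onset_s"].to_numpy() * fs).astype(int)
    data = np.stack([rec.samples[:, s + i0 : s + i1 + 1] for s in onsets])
    meta = make_trial_meta(
        events["onset_s"], events["back"], events["is_target"],
        events["response"], events["correct"], events["rt_s"],
    )
    return EpochedEEG(
        data=data,
        times=times,
        sampling_rate=fs,
        channel_names=list(rec.channel_names),
        trial_meta=meta,
    )


def simulate_eeg_dataset(cfg: SimConfig) -> tuple[list[EpochedEEG], np.ndarray]:
    """Generate the full cohort: per-subject epochs and group labels.

    Returns ``(subjects, groups)`` where ``groups[i]`` is 0 (lower capacity)
    or 1 (higher capacity) and subjects alternate group order 0,1,0,1,... so
    truncating the cohort keeps it balanced.
    """
    rng = np.random.default_rng(cfg.seed)
    subjects: list[EpochedEEG] = []
    groups = []
    for s in range(2 * cfg.n_subjects_per_group):
        group = s % 2
        rec, events = simulate_raw_subject(cfg, group, rng)
        subjects.append(_epoch_direct(rec, events, cfg.epoch_window))
        groups.append(group)
    return subjects, np.array(groups)


# ---------------------------------------------------------------------------
# behaviour


def simulate_behavior(
    params: BehaviorSimParams,
    n_subjects: int,
    backs: tuple[int, ...] = (3, 4),
    blocks: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Per subject x back x block behavioural summaries.

    target-ACC is drawn binomially from ``params.n_targets`` target trials
    with mean = clamped base + block_gain*(block-1), low performers (group 0)
    receiving an additional ``lp_extra_gain`` per block and high performers a
    ``hp_base_boost`` baseline advantage; RT is lognormal with a
    back-dependent location.
    """
    if not backs or not blocks:
        raise ValueError("backs and blocks must be non-empty")
    if not set(backs) <= {3, 4, 5}:
        raise ValueError("backs must be a subset of {3, 4, 5}")
    if not set(blocks) <= {1, 2, 3}:
        raise ValueError("blocks must be a subset of {1, 2, 3}")
    for b in backs:
        if b not in params.base_acc_by_back:
            raise ValueError(f"no base accuracy configured for back={b}")

    rng = np.random.default_rng(params.seed)
    rows = []
    for s in range(n_subjects):
        group = s % 2  # 0 = LP, 1 = HP
        for back in backs:
            for block in blocks:
                p = params.base_acc_by_back[back] + params.block_gain * (block - 1)
                if group == 0:
                    p += params.lp_extra_gain * (block - 1)
                else:
                    p += params.hp_base_boost
                p = float(np.clip(p, *ACC_CLAMP))
                hits = rng.binomial(params.n_targets, p)
                loc = params.rt_mean_s + params.back_rt_slope * (back - min(backs))
                rt = float(np.exp(rng.normal(np.log(loc), params.rt_sd_s / loc)))
                rows.append(
                    {
                        "subject": s,
                        "group": group,
                        "block": block,
                        "back": back,
                        "target_acc": hits / params.n_targets,
                        "rt_s": round(rt, 4),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# graph batches for the network stage


def make_planted_graph_batch(
    n_samples: int = 200,
    n_nodes: int = 64,
    informative_nodes: tuple[int, int] = (0, 1),
    effect: float = 4.0,
    node_boost: float = 2.0,
    rho: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Node-feature batch with two discriminative, mutually correlated nodes.

    Features emulate per-channel band power: per-node scalars (shape
    ``(n_samples, n_nodes, 1)``) of unit Gaussian noise, with the
    informative nodes elevated by ``node_boost`` in both classes (planted
    oscillatory power is present in both groups) plus a class-coded shift of
    ±``effect``/2, driven by a shared latent factor with correlation ``rho``
    between the two nodes.  Labels are balanced 0/1.
    """
    rng = np.random.default_rng(seed)
    labels = np.arange(n_samples) % 2
    x = rng.standard_normal((n_samples, n_nodes))
    latent = rng.standard_normal(n_samples)
    for node in informative_nodes:
        own = rng.standard_normal(n_samples)
        shared = np.sqrt(rho) * latent + np.sqrt(1 - rho) * own
        x[:, node] = node_boost + shared + np.where(labels == 1, effect / 2, -effect / 2)
    return x[:, :, None], labels


# ---------------------------------------------------------------------------
# fixture bundle


def make_small_fixture(seed: int, out_dir: str | Path) -> dict:
    """Write a small complete bundle (EEG + events + behaviour + manifest).

    4 subjects (2 per group), 10 trials each, EDF per subject with a sidecar
    tab-separated event table, a behaviour table and a ``key: value``
    manifest.  Identical seeds produce byte-identical bundles.
    """
    return write_bundle(
        SimConfig(n_subjects_per_group=2, n_trials_per_class=10, seed=seed), out_dir
    )


def write_bundle(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic bundle for an arbitrary cohort config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    rng = np.random.default_rng(cfg.seed)

    subject_files = []
    n_trials_total = 0
    for s in range(2 * cfg.n_subjects_per_group):
        group = s % 2
        rec, events = simulate_raw_subject(cfg, group, rng)
        edf_path = out / f"sub-{s:02d}_eeg.edf"
        write_edf(edf_path, rec, recording_id=f"synthetic sub-{s:02d}")
        ev_path = out / f"sub-{s:02d}_events.tsv"
        cols = ["onset_s", "back", "is_target", "response", "correct", "rt_s"]
        events[cols].to_csv(ev_path, sep="\t", index=False)
        subject_files.append((s, group, edf_path.name, ev_path.name))
        n_trials_total += len(events)

    beh = simulate_behavior(
        BehaviorSimParams(seed=seed), n_subjects=2 * cfg.n_subjects_per_group
    )
    beh_path = out / "behavior.tsv"
    beh.to_csv(beh_path, sep="\t", index=False)

    manifest = io.StringIO()
    print("bundle: neuromode synthetic fixture", file=manifest)
    print(f"seed: {seed}", file=manifest)
    print(f"n_subjects: {2 * cfg.n_subjects_per_group}", file=manifest)
    print(f"n_trials_total: {n_trials_total}", file=manifest)
    print(f"sampling_rate_hz: {cfg.sampling_rate:g}", file=manifest)
    print(f"n_channels: {cfg.n_channels}", file=manifest)
    print(f"epoch_window_s: {cfg.epoch_window[0]:g} {cfg.epoch_window[1]:g}", file=manifest)
    print(f"planted_freq_hz: {cfg.planted_freq:g}", file=manifest)
    print(f"planted_channels: {' '.join(cfg.planted_channels)}", file=manifest)
    print("behavior_file: behavior.tsv", file=manifest)
    for s, group, edf_name, ev_name in subject_files:
        print(f"subject_{s:02d}: group={group} eeg={edf_name} events={ev_name}", file=manifest)
    (out / "manifest.txt").write_text(manifest.getvalue())

    return {
        "dir": out,
        "manifest": out / "manifest.txt",
        "subjects": subject_files,
        "behavior": beh_path,
        "n_trials_total": n_trials_total,
        "config": cfg,
    }


def read_manifest(path: str | Path) -> dict[str, str]:
    """Parse a ``key: value`` manifest file into a dict."""
    result: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if ":" in line:
            key, val = line.split(":", 1)
            result[key.strip()] = val.strip()
    return result
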