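"""Filter-bank CSP with mutual-information mode selection.

The stage band-passes epochs into a small filter bank (theta 4-8, alpha
8-13, beta 13-30 Hz by default, gamma 30-48 optional), fits one set of
common spatial patterns per band by jointly diagonalising the two class
covariance matrices, forms normalised log-variance features

    X_p = log( var(Z_p) / sum_p' var(Z_p') ),   Z = W E,

and ranks the retained 2m components of every band by the mutual
information I(X; L) = H(X) - H(X|L) (bits) between the feature and the
binary capacity label (0 = lower capacity, 1 = higher capacity).  The top
modes name the discriminative (band, component) pairs; the corresponding
columns of W^-1 are the spatial patterns used for scalp topographies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import EpochedEEG
from .preprocess import bandpass
from .containers import RawRecording


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: ({self.low}, {self.high})")


DEFAULT_BANK = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)
GAMMA_BAND = BandDefinition("gamma", 30.0, 48.0)


@dataclass
class CSPModel:
    """Spatial filters for one frequency band.

    ``filters`` rows are spatial filters (components x channels); ``patterns``
    columns are the corresponding scalp patterns (channels x components,
    the inverse of the filter matrix).  ``eigenvalues[p]`` is the class-0
    share of the p-th component's variance, sorted descending, in [0, 1].
    ``m`` components are retained from each end (2m total).
    """

    band: BandDefinition
    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    m: int
    channel_names: list[str]

    @property
    def kept_components(self) -> np.ndarray:
        n = self.filters.shape[0]
        return np.r_[np.arange(self.m), np.arange(n - self.m, n)]


def filter_bank(
    ep: EpochedEEG, bands: tuple[BandDefinition, ...] = DEFAULT_BANK
) -> dict[str, EpochedEEG]:
    """Band-limited copies of the epochs, one per filter-bank band."""
    nyq = ep.sampling_rate / 2.0
    out: dict[str, EpochedEEG] = {}
    for band in bands:
        if band.high >= nyq:
            raise ValueError(f"band {band.name} exceeds Nyquist ({nyq} Hz)")
        # filter epochs channel-wise by treating trials*channels as rows
        flat = ep.data.reshape(-1, ep.data.shape[2])
        rec = RawRecording(
            samples=flat, sampling_rate=ep.sampling_rate,
            channel_names=[f"r{i}" for i in range(flat.shape[0])],
        )
        filt = bandpass(rec, band.low, band.high).samples.reshape(ep.data.shape)
        out[band.name] = ep.copy_with(data=filt)
    return out


def _class_covariance(data: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Average of trace-normalised per-trial sample covariances."""
    n_trials, n_ch, _ = data.shape
    cov = np.zeros((n_ch, n_ch))
    for trial in data:
        c = trial @ trial.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("zero-variance trial; cannot normalise covariance")
        cov += c / tr
    cov /= n_trials
    if ridge > 0:
        cov = cov + ridge * np.eye(n_ch)
    return cov


def fit_csp(
    ep0: EpochedEEG,
    ep1: EpochedEEG,
    m: int = 2,
    ridge: float = 0.0,
    window: tuple[float, float] | None = (0.0, 1.5),
    band: BandDefinition | None = None,
) -> CSPModel:
    """Fit CSP filters discriminating two classes of epochs.

    Solves the generalized eigenproblem C0 w = lambda (C0 + C1) w on the
    normalised average class covariances (equivalent to whitening + rotation)
    and orders components by descending class-0 variance ratio, so the first
    m components maximise class-0 variance and the last m maximise class-1
    variance.  ``window`` restricts the covariance estimate to the
    post-stimulus interval.
    """
    if ep0.channel_names != ep1.channel_names:
        raise ValueError("class epochs must share the same channels")
    if ep0.n_trials < 2 or ep1.n_trials < 2:
        raise ValueError("each class needs at least 2 trials")

    def _windowed(ep: EpochedEEG) -> np.ndarray:
        if window is None:
            return ep.data
        mask = (ep.times >= window[0]) & (ep.times <= window[1])
        return ep.data[:, :, mask]

    c0 = _class_covariance(_windowed(ep0), ridge)
    c1 = _class_covariance(_windowed(ep1), ridge)
    comp = c0 + c1
    # guard: generalized eigensolver needs a positive definite composite
    min_eig = np.linalg.eigvalsh(comp).min()
    if min_eig < 1e-10 * np.trace(comp) / comp.shape[0]:
        raise np.linalg.LinAlgError(
            "rank-deficient covariance; consider a ridge term (fit_csp(..., ridge=eps))"
        )
    eigvals, eigvecs = scipy.linalg.eigh(c0, comp)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, 1.0)
    filters = eigvecs[:, order].T  # rows = spatial filters
    patterns = np.linalg.inv(filters)  # columns = spatial patterns
    if m * 2 > filters.shape[0]:
        raise ValueError(f"m={m} too large for {filters.shape[0]} channels")
    return CSPModel(
        band=band if band is not None else BandDefinition("broadband", 1e-6, 1e6),
        filters=filters,
        patterns=patterns,
        eigenvalues=eigvals,
        m=m,
        channel_names=list(ep0.channel_names),
    )


def apply_csp(model: CSPModel, ep: EpochedEEG) -> np.ndarray:
    """Project epochs through the retained 2m spatial filters: Z = W E.

    Returns an array of shape (trials, 2m, samples).
    """
    if ep.channel_names != model.channel_names:
        raise ValueError("channel names do not match the fitted CSP model")
    w = model.filters[model.kept_components]
    return np.einsum("kc,tcs->tks", w, ep.data)


def extract_features(z: np.ndarray) -> np.ndarray:
    """Normalised log-variance features per trial.

    X_p = log(var(Z_p) / sum_p var(Z_p)); exp(X) sums to 1 over components
    and every X is <= 0.
    """
    var = z.var(axis=2, ddof=0) if z.ndim == 3 else np.atleast_2d(z.var(axis=-1, ddof=0))
    if np.any(var <= 0):
        raise ValueError("zero-variance component; cannot form log-variance feature")
    return np.log(var / var.sum(axis=1, keepdims=True))


def mutual_information(
    x: np.ndarray,
    labels: np.ndarray,
    bins: int | None = None,
    strategy: str = "width",
    correction: bool = False,
) -> float:
    """Histogram (plug-in) mutual information I(X; L) in bits.

    ``correction=True`` applies the Miller-Madow small-sample bias
    correction to each entropy term (the plug-in estimate is biased upward
    by roughly (bins-1)(classes-1)/(2 n ln 2) under independence).

    X is discretised with a histogram of ``bins`` bins (Sturges' rule,
    ceil(log2 n)+1, unless given); ``strategy='width'`` uses equal-width
    bins over the sample range, ``strategy='quantile'`` places the edges at
    sample quantiles (equal-frequency bins, a lower-variance discretiser
    whose edges do not chase range outliers).  Entropies are computed on the
    empirical bin probabilities in log base 2 and the estimate is clipped at
    zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if x.size != labels.size:
        raise ValueError("x and labels must have equal length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels contain a single class; MI is undefined")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    n = x.size
    if bins is None:
        bins = int(np.ceil(np.log2(n))) + 1
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 0.0  # constant feature carries no information
    if strategy == "width":
        edges = np.linspace(lo, hi, bins + 1)
    elif strategy == "quantile":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
        if edges.size < 2:
            return 0.0
    else:
        raise ValueError(f"unknown discretisation strategy {strategy!r}")

    def _entropy(counts: np.ndarray) -> float:
        total = counts.sum()
        p = counts[counts > 0] / total
        h = float(-(p * np.log2(p)).sum())
        if correction:
            h += (p.size - 1) / (2.0 * total * np.log(2.0))
        return h

    h_x = _entropy(np.histogram(x, bins=edges)[0])
    h_x_given_l = 0.0
    for c in classes:
        xc = x[labels == c]
        h_x_given_l += (xc.size / n) * _entropy(np.histogram(xc, bins=edges)[0])
    return max(h_x - h_x_given_l, 0.0)


def rank_modes(
    features_by_band: dict[str, np.ndarray],
    labels: np.ndarray,
    band_order: dict[str, float] | None = None,
    bins: int | None = None,
    strategy: str = "width",
) -> pd.DataFrame:
    """MI ranking over every (band, component) feature.

    ``features_by_band[band]`` is (samples x 2m); ``labels`` are the binary
    capacity labels aligned with the samples.  Rows are sorted by MI
    descending with a deterministic tie-break: lower band frequency first,
    then lower component index.
    """
    rows = []
    for band, feats in features_by_band.items():
        low = band_order.get(band, np.inf) if band_order else np.inf
        for p in range(feats.shape[1]):
            mi = mutual_information(feats[:, p], labels, bins=bins, strategy=strategy)
            rows.append({"band": band, "component": p, "mi_bits": mi, "_band_low": low})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["mi_bits", "_band_low", "component"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_band_low")


def select_top_modes(ranking: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Top-k (band, component) modes by MI (ranking is already tie-broken)."""
    if len(ranking) == 0:
        raise ValueError("empty MI ranking")
    if k > len(ranking):
        import logging

        logging.getLogger(__name__).warning(
            "requested top %d of %d modes; returning all", k, len(ranking)
        )
        k = len(ranking)
    return ranking.iloc[:k].reset_index(drop=True)


def pattern_topography(model: CSPModel, component: int) -> pd.DataFrame:
    """Channel weights of one spatial pattern, max-|.|-normalised.

    ``component`` indexes the retained 2m set (0..2m-1, the CSP0..CSP{2m-1}
    numbering of the feature vector): the first m entries are the strongest
    class-0-variance components, the last m the strongest class-1 ones.
    """
    kept = model.kept_components
    if not 0 <= component < kept.size:
        raise ValueError(
            f"component {component} is outside the retained set 0..{kept.size - 1}"
        )
    col = model.patterns[:, kept[component]]
    peak = np.abs(col).max()
    if peak == 0:
        raise ValueError("degenerate all-zero pattern")
    return pd.DataFrame(
        {"channel": model.channel_names, "weight": col / peak}
    )
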