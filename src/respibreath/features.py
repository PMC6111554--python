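"""Scalar feature extraction over breath windows and tree-based selection.

Thirteen feature families are computed on six series per breath: the raw
3-s window of each of the three bands and each window's first difference.
The families are the time- and frequency-domain statistics that carry the
quiet-vs-speech breathing contrast: dispersion-tail ratios, distribution
symmetry, wavelet-transform peak counts, skewness, chunked energy ratios,
the augmented Dickey-Fuller statistic, mean-crossing counts, Fourier and
autoregressive coefficients, Welch spectral density and sample entropy.

Feature names encode full provenance, e.g.
``upper_chest.deriv.fourier_coefficients.real_3``: band, raw/derivative,
family, parameter.  The name set is identical for every window, so windows
assemble directly into a feature matrix.

Selection ranks features by Gini importance of a random-forest ranker
fitted per cross-validation fold, averages importances across folds and
keeps the top fraction (default 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from statsmodels.tsa.ar_model import AutoReg
from statsmodels.tsa.stattools import adfuller

from .breathing import BreathEvent
from .errors import StratificationError
from .signal_io import ResistanceRecording

FAMILY_NAMES = (
    "ratio_beyond_r_sigma",
    "symmetry_looking",
    "cwt_peaks",
    "skewness",
    "energy_ratio_by_chunks",
    "adf",
    "count_above_mean",
    "count_below_mean",
    "number_crossings",
    "fourier_coefficients",
    "welch_density",
    "sample_entropy",
    "ar_coefficients",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Per-family parameters; defaults are fixed, documented package choices."""

    sigma_ratios: tuple[float, ...] = (1.0, 2.0)
    chunk_count: int = 10
    crossing_level: float = 0.0
    fft_coefficient_count: int = 10
    cwt_widths: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    cwt_rel_prominence: float = 0.1   # fraction of each scale row's range
    sampen_m: int = 2
    sampen_r: float = 0.2             # tolerance as fraction of series SD
    ar_order: int = 4
    symmetry_r: float = 0.25
    welch_nperseg: int = 256
    welch_coefficients: tuple[int, ...] = (2, 5, 8)
    adf_max_lag: int = 4

    def __post_init__(self):
        if self.chunk_count < 1 or self.fft_coefficient_count < 1 or self.ar_order < 1:
            raise ValueError("counts must be positive")
        if self.sampen_r <= 0 or self.sampen_m < 1:
            raise ValueError("sampen_m >= 1 and sampen_r > 0 required")


# ---------------------------------------------------------------------------
# individual families; each returns an ordered {suffix: value} dict


def _ratio_beyond_r_sigma(x, cfg):
    mu, sd = x.mean(), x.std()
    out = {}
    for r in cfg.sigma_ratios:
        if sd == 0:
            out[f"r_{r:g}"] = 0.0
        else:
            out[f"r_{r:g}"] = float(np.mean(np.abs(x - mu) > r * sd))
    return out

def _symmetry_looking(x, cfg):
    span = x.max() - x.min()
    val = float(abs(x.mean() - np.median(x)) < cfg.symmetry_r * span) if span > 0 else 1.0
    return {f"r_{cfg.symmetry_r:g}": val}

def _cwt_peaks(x, cfg):
    """Peaks of the Mexican-hat CWT, counted per scale with a relative
    prominence floor and summed over scales."""
    coeffs, _ = pywt.cwt(x, cfg.cwt_widths, "mexh")
    total = 0
    for row in coeffs:
        span = row.max() - row.min()
        if span == 0:
            continue
        pk, _ = signal.find_peaks(row, prominence=cfg.cwt_rel_prominence * span)
        total += len(pk)
    return {"n": float(total)}

def _skewness(x, cfg):
    if x.std() == 0:
        return {"g1": np.nan}
    return {"g1": float(stats.skew(x, bias=False))}

def _energy_ratio_by_chunks(x, cfg):
    total = float(np.sum(x**2))
    chunks = np.array_split(x, cfg.chunk_count)
    out = {}
    for i, chunk in enumerate(chunks):
        out[f"chunk_{i}"] = float(np.sum(chunk**2) / total) if total > 0 else np.nan
    return out

def _adf(x, cfg):
    if x.std() == 0 or len(x) <= cfg.adf_max_lag + 2:
        return {"stat": np.nan}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat = adfuller(x, maxlag=cfg.adf_max_lag, autolag=None)[0]
    return {"stat": float(stat)}

def _count_above_mean(x, cfg):
    return {"n": float(np.sum(x > x.mean()))}

def _count_below_mean(x, cfg):
    return {"n": float(np.sum(x < x.mean()))}

def _number_crossings(x, cfg):
    # sign changes of (x - m); samples exactly on m are dropped first,
    # so touching the level without crossing it does not count
    s = np.sign(x - cfg.crossing_level)
    s = s[s != 0]
    return {f"m_{cfg.crossing_level:g}": float(np.sum(s[1:] != s[:-1]))}

def _fourier_coefficients(x, cfg):
    coeffs = np.fft.rfft(x)
    out = {}
    for k in range(cfg.fft_coefficient_count):
        c = coeffs[k] if k < len(coeffs) else 0.0
        out[f"real_{k}"] = float(np.real(c))
        out[f"imag_{k}"] = float(np.imag(c))
    return out

def _welch_density(x, cfg):
    nperseg = min(len(x), cfg.welch_nperseg)
    _, pxx = signal.welch(x, nperseg=nperseg)
    out = {}
    for k in cfg.welch_coefficients:
        out[f"coeff_{k}"] = float(pxx[k]) if k < len(pxx) else np.nan
    return out

def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with B the number of template pairs of
    length ``m`` within Chebyshev distance r = ``r_frac``*SD(x), and A the
    count of those that still match at length m+1.  Self-matches excluded.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    if n <= m + 1 or sd == 0:
        return np.nan
    r = r_frac * sd

    # Chebyshev template distances built incrementally: dm[i, j] is the
    # distance between the length-m templates starting at i and j.  Both
    # counts run over the first n-m templates (each length-m template must
    # extend to length m+1), the Richman-Moorman convention.
    d1 = np.abs(x[:, None] - x[None, :])
    nt = n - m
    dm = d1[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(dm, d1[k : k + nt, k : k + nt], out=dm)

    def _pairs(d: np.ndarray) -> int:
        matches = np.sum(d <= r)  # includes self-matches and both orderings
        return int((matches - len(d)) // 2)

    b = _pairs(dm)
    dm1 = np.maximum(dm, d1[m : m + nt, m : m + nt])
    a = _pairs(dm1)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))

def _sample_entropy(x, cfg):
    return {f"m_{cfg.sampen_m}": sample_entropy(x, cfg.sampen_m, cfg.sampen_r)}

def _ar_coefficients(x, cfg):
    k = cfg.ar_order
    if x.std() == 0 or len(x) <= 2 * k + 1:
        return {"const": np.nan, **{f"lag_{i}": np.nan for i in range(1, k + 1)}}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = AutoReg(x, lags=k, old_names=False).fit().params
    out = {"const": float(params[0])}
    for i in range(1, k + 1):
        out[f"lag_{i}"] = float(params[i])
    return out


_FAMILY_FUNCS = {
    "ratio_beyond_r_sigma": _ratio_beyond_r_sigma,
    "symmetry_looking": _symmetry_looking,
    "cwt_peaks": _cwt_peaks,
    "skewness": _skewness,
    "energy_ratio_by_chunks": _energy_ratio_by_chunks,
    "adf": _adf,
    "count_above_mean": _count_above_mean,
    "count_below_mean": _count_below_mean,
    "number_crossings": _number_crossings,
    "fourier_coefficients": _fourier_coefficients,
    "welch_density": _welch_density,
    "sample_entropy": _sample_entropy,
    "ar_coefficients": _ar_coefficients,
}


def first_derivative(x: np.ndarray) -> np.ndarray:
    """First difference x[i+1] - x[i]; length n-1."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.diff(x)


def compute_scalar_feature(
    name: str, x: np.ndarray, cfg: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Evaluate one family on a series; returns ``{parameter-suffix: value}``.

    Degenerate inputs (e.g. zero variance where variance is required)
    yield NaN values that the imputation step downstream replaces.
    """
    if name not in _FAMILY_FUNCS:
        raise ValueError(f"unknown feature family {name!r}")
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("series too short")
    return _FAMILY_FUNCS[name](x, cfg)


def compute_feature_vector(
    event: BreathEvent,
    rec: ResistanceRecording,
    cfg: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """All families on raw + first-derivative windows of all three bands.

    Returns an ordered name->value mapping; names are identical across
    events, so rows stack into a matrix.
    """
    if event.window_start < 0 or event.window_end > rec.n_samples:
        raise ValueError("event window lies outside the recording")
    out: dict[str, float] = {}
    for channel, series in rec.channels.items():
        window = series[event.window_start : event.window_end]
        for series_name, data in (("raw", window), ("deriv", first_derivative(window))):
            for family in FAMILY_NAMES:
                for suffix, value in compute_scalar_feature(family, data, cfg).items():
                    out[f"{channel}.{series_name}.{family}.{suffix}"] = value
    return out


def feature_matrix(
    events: list[BreathEvent],
    rec: ResistanceRecording,
    cfg: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature matrix with one row per breath event plus a ``label`` column."""
    rows = [compute_feature_vector(e, rec, cfg) for e in events]
    frame = pd.DataFrame(rows)
    frame["label"] = [e.label for e in events]
    return frame


def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 15,
    top_fraction: float = 0.10,
    seed: int = 0,
    n_trees: int = 100,
) -> list[str]:
    """Top-``top_fraction`` features by fold-averaged Gini importance.

    A random-forest ranker is fitted on the training part of each
    stratified fold; importances are averaged over folds and the top
    fraction of feature names returned, ties broken by name.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise StratificationError("both classes required for feature selection")
    counts = np.bincount(y.astype(int))
    if counts.min() < n_folds:
        raise StratificationError(
            f"minority class ({counts.min()}) smaller than n_folds ({n_folds})"
        )
    Xv = X.fillna(X.median()).to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    importances = np.zeros(X.shape[1])
    for train_idx, _ in skf.split(Xv, y):
        ranker = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        ranker.fit(Xv[train_idx], y[train_idx])
        importances += ranker.feature_importances_
    importances /= n_folds
    n_keep = max(1, int(np.ceil(top_fraction * X.shape[1])))
    order = sorted(zip(-importances, X.columns))  # descending importance, name tie-break
    return [name for _, name in order[:n_keep]]
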