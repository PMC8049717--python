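"""Autocorrelation and automutual-information features.

The autocorrelation is the biased, variance-normalized estimate (lag 0 = 1).
Automutual information is estimated with quantile-edge histograms in nats and
clamped at zero (the plug-in estimator can go slightly negative).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np


def acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased normalized autocorrelation at lags 0..max_lag via FFT.

    Returns NaNs for zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= max_lag:
        raise ValueError("series must be longer than max_lag")
    xc = x - x.mean()
    var = np.dot(xc, xc)
    if var == 0.0:
        return np.full(max_lag + 1, np.nan)
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(xc, nfft)
    r = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return r / var


def first_zero_acf(x: np.ndarray, max_lag: Optional[int] = None) -> float:
    """Smallest lag at which the autocorrelation first crosses <= 0."""
    x = np.asarray(x, dtype=float)
    if max_lag is None:
        max_lag = min(x.size - 2, 400)
    r = acf(x, max_lag)
    if np.any(np.isnan(r)):
        return np.nan
    hits = np.nonzero(r[1:] <= 0.0)[0]
    return float(hits[0] + 1) if hits.size else np.nan


def acf_features(
    x: np.ndarray,
    max_lag: int = 33,
    lags: Sequence[int] = (1, 2, 3, 5, 14, 33),
) -> Dict[str, float]:
    x = np.asarray(x, dtype=float)
    out: Dict[str, float] = {}
    r = acf(x, max_lag) if x.size > max_lag else np.full(max_lag + 1, np.nan)
    for lag in lags:
        out[f"acf_lag{lag}"] = float(r[lag]) if lag <= max_lag else np.nan
    out["acf_first_zero"] = first_zero_acf(x)
    return out


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    return edges


def ami(x: np.ndarray, lag: int, n_bins: int = 8) -> float:
    """Histogram automutual information (nats) between x_t and x_{t+lag}."""
    x = np.asarray(x, dtype=float)
    if lag < 0 or x.size - lag < 4 * n_bins:
        return np.nan
    if np.ptp(x) == 0.0:
        return np.nan
    a = x[: x.size - lag] if lag else x
    b = x[lag:] if lag else x
    edges = _quantile_edges(x, n_bins)
    h, _, _ = np.histogram2d(a, b, bins=(edges, edges))
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    mi = float(np.sum(p[nz] * (np.log(p[nz]) - np.log(np.outer(px, py)[nz]))))
    return max(mi, 0.0)


def first_min_ami(x: np.ndarray, max_lag: int = 40, n_bins: int = 8) -> float:
    """Lag of the first local minimum of the AMI curve over lags 1..max_lag."""
    vals = [ami(x, lag, n_bins) for lag in range(1, max_lag + 1)]
    if any(np.isnan(v) for v in vals[:2]):
        return np.nan
    for i in range(1, len(vals)):
        if np.isnan(vals[i]):
            break
        if vals[i] > vals[i - 1]:
            return float(i)
    return np.nan


def ami_features(
    x: np.ndarray,
    lags: Sequence[int] = (1, 2, 3),
    n_bins: int = 8,
    noise_levels: Sequence[float] = (0.25, 0.5, 1.0, 1.5, 2.0),
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """AMI at fixed lags, first-minimum lag, and AMI decay under added noise.

    The noise slope regresses AMI(lag 1) on the amplitude (in units of the
    series sd) of seeded white Gaussian noise added to the series.
    """
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    out: Dict[str, float] = {}
    for lag in lags:
        out[f"ami_lag{lag}"] = ami(x, lag, n_bins)
    out["ami_first_min"] = first_min_ami(x, n_bins=n_bins)
    sd = float(np.std(x))
    if sd == 0.0 or np.isnan(out.get("ami_lag1", np.nan)):
        out["ami_noise_slope"] = np.nan
        return out
    amis = []
    for lev in noise_levels:
        noisy = x + rng.normal(0.0, lev * sd, size=x.size)
        amis.append(ami(noisy, 1, n_bins))
    levels = np.asarray(noise_levels, dtype=float)
    out["ami_noise_slope"] = float(np.polyfit(levels, np.asarray(amis), 1)[0])
    return out
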