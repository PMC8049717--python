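"""Stationarity and iterated-preprocessing features.

Stationarity is summarized two ways: the spread of basic moments across
randomly placed local windows (a bootstrap-style measure), and the
comparison of a central window's statistics against the whole series. A
separate operation tracks how probe statistics evolve as the series is
repeatedly differenced.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy import stats

from .correlation import acf
from .spectral import psd


def stationarity_features(
    x: np.ndarray,
    window_fraction: float = 0.1,
    n_boot: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Spread of local moments across random windows + local/global ratios.

    The spread features are the standard deviation, across ``n_boot`` random
    contiguous windows of length ``window_fraction * N``, of the window mean,
    sd, skewness and kurtosis. The local/global features compare the central
    window to the whole series: mean and median use the absolute difference
    scaled by the global sd (0 for a constant series), sd and IQR use ratios,
    skewness and kurtosis use differences.
    """
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    n = x.size
    wlen = int(round(window_fraction * n))
    if wlen > n:
        raise ValueError("window longer than series")
    if wlen < 20:
        raise ValueError("window must span at least 20 samples")
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")

    starts = rng.integers(0, n - wlen + 1, size=n_boot)
    wins = np.stack([x[s : s + wlen] for s in starts])
    out: Dict[str, float] = {
        "stat_spread_mean": float(wins.mean(axis=1).std()),
        "stat_spread_sd": float(wins.std(axis=1).std()),
        "stat_spread_skew": float(np.std(stats.skew(wins, axis=1))),
        "stat_spread_kurt": float(np.std(stats.kurtosis(wins, axis=1))),
    }

    mid = x[(n - wlen) // 2 : (n - wlen) // 2 + wlen]
    gsd = float(x.std())
    giqr = float(stats.iqr(x))
    out["localglobal_mean"] = float(abs(mid.mean() - x.mean()) / gsd) if gsd > 0 else 0.0
    out["localglobal_median"] = (
        float(abs(np.median(mid) - np.median(x)) / gsd) if gsd > 0 else 0.0
    )
    out["localglobal_sd"] = float(mid.std() / gsd) if gsd > 0 else np.nan
    out["localglobal_iqr"] = float(stats.iqr(mid) / giqr) if giqr > 0 else np.nan
    out["localglobal_skew"] = (
        float(stats.skew(mid) - stats.skew(x)) if gsd > 0 else np.nan
    )
    out["localglobal_kurt"] = (
        float(stats.kurtosis(mid) - stats.kurtosis(x)) if gsd > 0 else np.nan
    )
    return out


def iterated_preprocess_compare(x: np.ndarray, rate_hz: float = 1.0) -> Dict[str, float]:
    """Trajectories of probe statistics under successive differencing.

    The series is differenced 1..3 times; after each pass the sd, lag-1
    autocorrelation and spectral median are recomputed. Features are the
    least-squares slopes of each three-point trajectory against iteration
    number (sd on a log scale relative to the original sd).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        return {
            k: np.nan
            for k in (
                "ppiter_sd_iter1",
                "ppiter_slope_sd",
                "ppiter_slope_acf1",
                "ppiter_slope_specmed",
            )
        }
    sd0 = x.std()
    sds, acf1s, smeds = [], [], []
    d = x
    for _ in range(3):
        d = np.diff(d)
        sds.append(d.std() / sd0 if sd0 > 0 else np.nan)
        r = acf(d, 1) if d.size > 2 and d.std() > 0 else [np.nan, np.nan]
        acf1s.append(float(r[1]))
        f, p = psd(d, rate_hz, "welch", "hamming")
        if np.all(np.isfinite(p)):
            smeds.append(float(np.interp(0.5, np.cumsum(p), f)) / (rate_hz / 2.0))
        else:
            smeds.append(np.nan)
    it = np.arange(1, 4)

    def slope(v):
        v = np.asarray(v, dtype=float)
        return float(np.polyfit(it, v, 1)[0]) if np.all(np.isfinite(v)) else np.nan

    return {
        "ppiter_sd_iter1": float(sds[0]),
        "ppiter_slope_sd": slope(sds),
        "ppiter_slope_acf1": slope(acf1s),
        "ppiter_slope_specmed": slope(smeds),
    }
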