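"""Power-spectral-density summary features.

The one-sided PSD is computed by one of three methods (Welch-averaged, a
single full-length windowed FFT, or the periodogram) under a Hamming or
rectangular window, normalized to unit sum, and then treated as a
probability distribution over frequency. The summaries are distributional:
median frequency, interquartile range and its log, centroid, peak frequency,
and the cumulative-power quartile frequencies.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy import signal

METHODS = ("welch", "fourier", "periodogram")
WINDOWS = ("hamming", "rectangular")


def psd(
    x: np.ndarray, rate_hz: float, method: str = "welch", window: str = "hamming"
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided PSD normalized to unit sum. Returns (freqs, density)."""
    x = np.asarray(x, dtype=float)
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    win = window if window == "hamming" else "boxcar"
    if method == "welch":
        nperseg = min(1024, x.size)
        f, p = signal.welch(x, fs=rate_hz, window=win, nperseg=nperseg)
    elif method == "periodogram":
        f, p = signal.periodogram(x, fs=rate_hz, window=win)
    else:  # full-length windowed FFT magnitude squared
        wv = signal.get_window(win, x.size)
        spec = np.fft.rfft(x * wv)
        p = np.abs(spec) ** 2
        f = np.fft.rfftfreq(x.size, d=1.0 / rate_hz)
    total = p.sum()
    if total == 0.0 or not np.isfinite(total):
        return f, np.full_like(p, np.nan)
    return f, p / total


def _quantile_freq(f: np.ndarray, cdf: np.ndarray, q: float) -> float:
    return float(np.interp(q, cdf, f))


def psd_summaries(
    x: np.ndarray, rate_hz: float, method: str = "welch", window: str = "hamming"
) -> Dict[str, float]:
    """Distributional summaries of the normalized PSD (all in Hz, log in nats)."""
    f, p = psd(x, rate_hz, method, window)
    prefix = f"psd_{method}_{window}"
    names = ("median", "iqr", "log_iqr", "centroid", "peak", "q25", "q75")
    if np.any(~np.isfinite(p)):
        return {f"{prefix}_{n}": np.nan for n in names}
    cdf = np.cumsum(p)
    q25 = _quantile_freq(f, cdf, 0.25)
    med = _quantile_freq(f, cdf, 0.5)
    q75 = _quantile_freq(f, cdf, 0.75)
    iqr = q75 - q25
    return {
        f"{prefix}_median": med,
        f"{prefix}_iqr": iqr,
        f"{prefix}_log_iqr": float(np.log(iqr)) if iqr > 0 else np.nan,
        f"{prefix}_centroid": float(np.sum(f * p)),
        f"{prefix}_peak": float(f[np.argmax(p)]),
        f"{prefix}_q25": q25,
        f"{prefix}_q75": q75,
    }


def psd_summaries_all(x: np.ndarray, rate_hz: float) -> Dict[str, float]:
    """Summaries for every method x window combination."""
    out: Dict[str, float] = {}
    for m in METHODS:
        for w in WINDOWS:
            out.update(psd_summaries(x, rate_hz, m, w))
    return out
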