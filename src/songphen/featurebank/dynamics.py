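"""Walker simulation, local forecasting, and successive-difference features."""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
from scipy import signal

from .symbolic import symbolize


def walker_features(x: np.ndarray, attraction: float = 0.1) -> Dict[str, float]:
    """Statistics of a hypothetical walker attracted to the series.

    The walker obeys w_{t+1} = w_t + attraction * (x_t - w_t) with
    w_1 = x_1 (a first-order lag: at attraction = 1 the walker reproduces the
    input delayed by one step; small attraction low-pass filters it).
    Features compare the walker's trajectory with the input.
    """
    if not (0.0 < attraction <= 1.0):
        raise ValueError("attraction must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    a = attraction
    # w[t] = (1-a) w[t-1] + a x[t-1]; realize via an IIR filter on x
    w = np.empty_like(x)
    w[0] = x[0]
    if x.size > 1:
        zi = signal.lfiltic([a], [1.0, -(1.0 - a)], [x[0]])
        w[1:] = signal.lfilter([a], [1.0, -(1.0 - a)], x[:-1], zi=zi)[0]
    d = w - x
    varx = x.var()
    p = f"walker_a{attraction:g}"
    return {
        f"{p}_mean_diff": float(d.mean()),
        f"{p}_var_ratio": float(w.var() / varx) if varx > 0 else np.nan,
        f"{p}_sign_asym": float(np.mean(np.sign(d))),
    }


def forecast_features(
    x: np.ndarray,
    train_windows: Sequence[int] = (1, 2, 4, 8, 16),
    memory: int = 3,
) -> Dict[str, float]:
    """Local mean-forecast error per window length, plus symbolic surprise.

    Mean forecasting predicts x_{t+1} as the mean of the previous L values;
    the RMSE (in units of the series sd) is reported per L together with the
    minimizing L. Surprise coarse-grains the series into 3 quantile symbols
    and scores the realized next symbol by the negative log of its
    probability under the empirical distribution of the preceding ``memory``
    symbols (Laplace add-one smoothing over the observed alphabet, applied
    only when more than one symbol exists).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if memory >= n:
        raise ValueError("memory must be smaller than the series length")
    if max(train_windows) + 1 >= n:
        raise ValueError("series too short for the largest training window")
    out: Dict[str, float] = {}
    sd = x.std()
    csum = np.concatenate(([0.0], np.cumsum(x)))
    rmses = []
    for L in train_windows:
        means = (csum[L:-1] - csum[:-L - 1]) / L  # mean of x[t-L..t-1] for t = L..n-1
        err = x[L:] - means
        rmse = float(np.sqrt(np.mean(err**2)))
        rmses.append(rmse)
        out[f"forecast_rmse_L{L}"] = rmse / sd if sd > 0 else (0.0 if rmse == 0 else np.nan)
    out["forecast_best_L"] = float(train_windows[int(np.argmin(rmses))])

    # symbolic surprise
    try:
        s = symbolize(x, 3)
    except ValueError:
        s = np.zeros(n, dtype=int) if np.ptp(x) == 0 else None
    if s is None:
        out["surprise_mean"] = np.nan
        return out
    alphabet = np.unique(s)
    k = alphabet.size
    if k == 1:
        out["surprise_mean"] = 0.0
        return out
    idx = np.searchsorted(alphabet, s)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), idx] = 1.0
    ccounts = np.cumsum(onehot, axis=0)
    counts = ccounts[memory - 1 : n - 1] - np.vstack(
        (np.zeros((1, k)), ccounts[: n - 1 - memory])
    )
    probs = (counts + 1.0) / (memory + k)
    realized = probs[np.arange(n - memory), idx[memory:]]
    out["surprise_mean"] = float(-np.mean(np.log(realized)))
    return out


def diffstats_hrv(
    x: np.ndarray, pnn_thresholds: Sequence[float] = (0.25, 0.5, 1.0)
) -> Dict[str, float]:
    """Heart-rate-variability-style statistics of successive differences.

    pNN-style fractions count |x_{t+1} - x_t| exceeding each threshold,
    thresholds expressed as multiples of the series sd; the RMSSD analogue is
    the root mean square of the differences.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(x)
    sd = x.std()
    out: Dict[str, float] = {}
    for thr in pnn_thresholds:
        out[f"pnn_{thr:g}sd"] = float(np.mean(np.abs(d) > thr * sd))
    out["rmssd"] = float(np.sqrt(np.mean(d**2)))
    out["sd_diff"] = float(d.std())
    return out
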