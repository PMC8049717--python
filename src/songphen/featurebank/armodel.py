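"""Autoregressive-model features.

AR(p) models are fit by conditional least squares for a range of orders;
features summarize order-selection criteria (Schwarz's Bayesian criterion,
Akaike's final prediction error), the selected order and its coefficients,
residual whiteness, the stability of one-step prediction error across local
segments, and multi-step prediction error as a function of horizon.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def fit_ar(x: np.ndarray, order: int) -> Tuple[np.ndarray, float]:
    """Least-squares AR(p) fit. Returns (coefficients a_1..a_p, residual var).

    The model is x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t on the
    mean-removed series.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    if n < 10 * order:
        raise ValueError("series too short for the requested order")
    X = sliding_window_view(x, order)[: n - order, ::-1]
    y = x[order:]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(np.mean(resid**2))


def _predict_multistep(x: np.ndarray, coef: np.ndarray, horizon: int) -> np.ndarray:
    """h-step-ahead predictions of x_t from the fitted AR recursion."""
    p = coef.size
    hist = [x]  # hist[j] holds the j-step prediction series aligned with x
    for h in range(1, horizon + 1):
        prev = np.full(x.size, np.nan)
        for j, a in enumerate(coef, start=1):
            # lag j of the (h-j)-step prediction (actual values when h <= j)
            src = hist[max(h - j, 0)]
            lagged = np.concatenate((np.full(j, np.nan), src[:-j]))
            prev = lagged * a if j == 1 else prev + lagged * a
        hist.append(prev)
    return hist[horizon]


def ar_features(
    x: np.ndarray,
    orders: Sequence[int] = (1, 2, 3, 4, 5, 6),
    horizons: Sequence[int] = (1, 2, 5, 10),
    n_segments: int = 5,
) -> Dict[str, float]:
    x = np.asarray(x, dtype=float)
    out: Dict[str, float] = {}
    n = x.size
    fits: Dict[int, Tuple[np.ndarray, float]] = {}
    sbcs: Dict[int, float] = {}
    for p in orders:
        try:
            coef, s2 = fit_ar(x, p)
        except (ValueError, np.linalg.LinAlgError):
            out[f"ar_sbc_p{p}"] = np.nan
            out[f"ar_fpe_p{p}"] = np.nan
            continue
        if s2 <= 0:
            out[f"ar_sbc_p{p}"] = np.nan
            out[f"ar_fpe_p{p}"] = np.nan
            continue
        fits[p] = (coef, s2)
        sbcs[p] = n * np.log(s2) + p * np.log(n)
        out[f"ar_sbc_p{p}"] = float(sbcs[p])
        out[f"ar_fpe_p{p}"] = float(s2 * (n + p + 1) / (n - p - 1))

    if not fits:
        for name in ("ar_best_order_sbc", "ar_phi1", "ar_resid_whiteness",
                     "ar_segment_rmse_mean", "ar_segment_rmse_spread"):
            out[name] = np.nan
        for h in horizons:
            out[f"ar_pred_rmse_h{h}"] = np.nan
        return out

    best = min(sbcs, key=lambda p: (sbcs[p], p))
    coef, s2 = fits[best]
    out["ar_best_order_sbc"] = float(best)
    out["ar_phi1"] = float(fits[min(fits)][0][0])

    # residual whiteness: sum of squared residual autocorrelations, lags 1-10
    xm = x - x.mean()
    X = sliding_window_view(xm, best)[: n - best, ::-1]
    resid = xm[best:] - X @ coef
    rc = resid - resid.mean()
    denom = np.dot(rc, rc)
    if denom > 0:
        acfs = [np.dot(rc[:-k], rc[k:]) / denom for k in range(1, 11)]
        out["ar_resid_whiteness"] = float(resid.size * np.sum(np.square(acfs)))
    else:
        out["ar_resid_whiteness"] = np.nan

    # one-step error of the global best model within equal local segments
    err = resid**2
    seg = np.array_split(err, n_segments)
    seg_rmse = np.array([np.sqrt(s.mean()) for s in seg if s.size])
    out["ar_segment_rmse_mean"] = float(seg_rmse.mean())
    out["ar_segment_rmse_spread"] = float(seg_rmse.std())

    # multi-step prediction RMSE at each horizon
    sd = x.std()
    for h in horizons:
        pred = _predict_multistep(xm, coef, h)
        ok = np.isfinite(pred)
        if ok.sum() < 10 or sd == 0:
            out[f"ar_pred_rmse_h{h}"] = np.nan
        else:
            out[f"ar_pred_rmse_h{h}"] = float(
                np.sqrt(np.mean((xm[ok] - pred[ok]) ** 2)) / sd
            )
    return out
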