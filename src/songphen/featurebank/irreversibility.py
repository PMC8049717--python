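"""Time-reversal asymmetry statistics.

A signal is time irreversible when its statistics differ from those of its
time-reversed copy; Gaussian linear processes are reversible, so nonzero
values flag nonlinear (non-Gaussian) temporal structure. Two statistics are
provided: a normalized cubed-increment statistic (``co_trev``) and a
three-column delay-embedding statistic (``dk_trev``). Both are signed so that
they respond in the same direction to the same asymmetry, and both return 0
for palindromic input and flip sign under time reversal.
"""

from __future__ import annotations

from typing import Dict, Sequence, Union

import numpy as np

from .correlation import first_min_ami, first_zero_acf

Lag = Union[int, str]


def co_trev(x: np.ndarray, tau: Lag = 1) -> float:
    """Normalized nonlinear autocorrelation of lagged increments.

    With increments d_n = x_{n-tau} - x_n taken over n = tau+1..N:

        trev(tau) = mean(d^3) / mean(d^2)^{3/2}

    ``tau`` may be a positive integer or one of ``"acf_zero"`` (first zero
    crossing of the autocorrelation) / ``"ami_min"`` (first minimum of the
    automutual information), which are resolved on the input first.

    Returns NaN when the increments are identically zero (constant or
    tau-periodic input), so degenerate features can be filtered downstream.
    """
    x = np.asarray(x, dtype=float)
    tau_i = _resolve_lag(x, tau)
    if np.isnan(tau_i):
        return np.nan
    tau_i = int(tau_i)
    if x.size <= tau_i + 1:
        return np.nan
    d = x[:-tau_i] - x[tau_i:]
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        return np.nan
    return float(np.mean(d**3) / m2**1.5)


def dk_trev(x: np.ndarray, tau: int = 1, M: int = 3) -> float:
    """Time-reversal asymmetry from a 3-column delay embedding.

    Builds the embedding with columns (x_t, x_{t+tau}, x_{t+2tau}) over
    t = 1..N-(M-1)tau and returns mean(a1*a1*a2 - a2*a3*a3), the elementwise
    product combination of the columns a1..a3. Only M = 3 is supported.
    """
    if M != 3:
        raise ValueError("only embedding dimension M = 3 is supported")
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    n = x.size - (M - 1) * tau
    if n < 1:
        return np.nan
    a1 = x[:n]
    a2 = x[tau : tau + n]
    a3 = x[2 * tau : 2 * tau + n]
    return float(np.mean(a1 * a1 * a2 - a2 * a3 * a3))


def _resolve_lag(x: np.ndarray, tau: Lag) -> float:
    if isinstance(tau, str):
        if tau == "acf_zero":
            return first_zero_acf(x)
        if tau == "ami_min":
            return first_min_ami(x)
        raise ValueError(f"unknown symbolic lag {tau!r}")
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    return float(tau)


def co_trev_features(
    x: np.ndarray, taus: Sequence[Lag] = (1, 2, 3, "acf_zero", "ami_min")
) -> Dict[str, float]:
    return {f"co_trev_tau{t}": co_trev(x, t) for t in taus}


def dk_trev_features(x: np.ndarray, taus: Sequence[int] = (1, 2, 3, 4)) -> Dict[str, float]:
    return {f"dk_trev_tau{t}": dk_trev(x, t) for t in taus}
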