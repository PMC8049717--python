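"""Symbolic-dynamics and ordinal-pattern features.

Continuous series are coarse-grained into k equiprobable-quantile symbols
(robust to amplitude scaling); features then summarize length-3 word
statistics, binary (above/below mean) run statistics, symbol transition
matrices and their change with alphabet size, and permutation entropy of
ordinal patterns.
"""

from __future__ import annotations

from math import factorial
from typing import Dict, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def symbolize(x: np.ndarray, k: int) -> np.ndarray:
    """Coarse-grain into k equiprobable-quantile symbols (0..k-1).

    Raises ValueError when the data cannot support k distinct quantile bins.
    """
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.linspace(0.0, 1.0, k + 1))[1:-1]
    if np.unique(edges).size < k - 1:
        raise ValueError(f"too few distinct values for {k} quantile bins")
    return np.searchsorted(edges, x, side="right")


def transition_matrix(symbols: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic first-order transition matrix between symbols."""
    s = np.asarray(symbols)
    counts = np.zeros((k, k))
    np.add.at(counts, (s[:-1], s[1:]), 1.0)
    rowsum = counts.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0.0] = 1.0
    return counts / rowsum


def _matrix_entropy(tm: np.ndarray) -> float:
    """Entropy (nats) of the stationary joint transition distribution."""
    joint = tm / tm.sum() if tm.sum() > 0 else tm
    nz = joint > 0
    return float(-np.sum(joint[nz] * np.log(joint[nz])))


def symbolic_features(
    x: np.ndarray, alphabet_sizes: Sequence[int] = (2, 3, 4, 5)
) -> Dict[str, float]:
    x = np.asarray(x, dtype=float)
    out: Dict[str, float] = {}

    # length-3 word statistics on the 3-letter alphabet
    try:
        s3 = symbolize(x, 3)
        words = s3[:-2] * 9 + s3[1:-1] * 3 + s3[2:]
        freq = np.bincount(words, minlength=27) / words.size
        nz = freq > 0
        out["motif3_entropy"] = float(-np.sum(freq[nz] * np.log(freq[nz])))
        out["motif3_max_freq"] = float(freq.max())
    except ValueError:
        out["motif3_entropy"] = np.nan
        out["motif3_max_freq"] = np.nan

    # binary above/below-mean run statistics
    b = (x > x.mean()).astype(int)
    runs = np.diff(np.flatnonzero(np.concatenate(([1], np.diff(b) != 0, [1]))))
    vals = b[np.concatenate(([0], np.cumsum(runs)[:-1]))]
    out["binary_longest_run0"] = float(runs[vals == 0].max()) if np.any(vals == 0) else 0.0
    out["binary_longest_run1"] = float(runs[vals == 1].max()) if np.any(vals == 1) else 0.0
    out["binary_mean_run"] = float(runs.mean())

    # transition-matrix statistics per alphabet size
    entropies = []
    for k in alphabet_sizes:
        names = [f"trans_k{k}_{n}" for n in ("max_offdiag", "min_offdiag", "trace", "entropy")]
        try:
            tm = transition_matrix(symbolize(x, k), k)
            off = tm[~np.eye(k, dtype=bool)]
            ent = _matrix_entropy(tm)
            vals_k = [float(off.max()), float(off.min()), float(np.trace(tm)), ent]
            entropies.append((k, ent))
        except ValueError:
            vals_k = [np.nan] * 4
        out.update(dict(zip(names, vals_k)))
    if len(entropies) >= 2:
        ks, es = zip(*entropies)
        out["trans_entropy_slope"] = float(np.polyfit(ks, es, 1)[0])
    else:
        out["trans_entropy_slope"] = np.nan
    return out


def ordinal_pattern_frequencies(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """Frequencies of the m! ordinal patterns at lag tau."""
    x = np.asarray(x, dtype=float)
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short for the requested order/lag")
    emb = sliding_window_view(x, (m - 1) * tau + 1)[:, :: tau]
    ranks = np.argsort(np.argsort(emb, axis=1, kind="stable"), axis=1, kind="stable")
    base = factorial(m)
    codes = np.zeros(emb.shape[0], dtype=np.int64)
    for j in range(m):
        codes = codes * m + ranks[:, j]
    freq = np.bincount(codes, minlength=m**m).astype(float)
    return freq[freq > 0] / emb.shape[0] if freq.sum() else np.array([])


def permutation_entropy(
    x: np.ndarray, m: int = 3, tau: int = 1, scales: Sequence[int] = (1,)
) -> Dict[str, float]:
    """Shannon entropy (nats) of ordinal-pattern frequencies, per time scale.

    Each scale applies non-overlapping mean coarse-graining before the
    ordinal analysis (multiscale permutation entropy). Values lie in
    [0, ln m!]; a strictly monotone series gives exactly 0.
    """
    x = np.asarray(x, dtype=float)
    out: Dict[str, float] = {}
    for scale in scales:
        if scale < 1:
            raise ValueError("scales must be positive integers")
        n_coarse = x.size // scale
        xs = x[: n_coarse * scale].reshape(n_coarse, scale).mean(axis=1) if scale > 1 else x
        key = f"perm_entropy_m{m}_scale{scale}"
        if xs.size < (m - 1) * tau + 2:
            out[key] = np.nan
            continue
        freq = ordinal_pattern_frequencies(xs, m, tau)
        out[key] = float(-np.sum(freq * np.log(freq))) if freq.size else np.nan
    return out
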