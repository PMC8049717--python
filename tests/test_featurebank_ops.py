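"""Unit tests for the remaining feature-bank operations."""

import math
from collections import Counter

import numpy as np
import pytest

from songphen.featurebank import (
    acf_features,
    ami,
    ami_features,
    ar_features,
    baseline_spectral_features,
    diffstats_hrv,
    fit_ar,
    forecast_features,
    iterated_preprocess_compare,
    ordinal_pattern_frequencies,
    permutation_entropy,
    preprocess_waveform,
    psd_summaries,
    stationarity_features,
    symbolic_features,
    symbolize,
    transition_matrix,
    walker_features,
)
from songphen.types import MotifWaveform


# ------------------------------------------------------------------ acf / ami

def test_acf_of_sine_is_periodic():
    period = 50
    x = np.sin(2 * np.pi * np.arange(5000) / period)
    out = acf_features(x, max_lag=period, lags=(1, period))
    assert out[f"acf_lag{period}"] >= 0.99
    assert acf_features(x)["acf_lag1"] <= 1.0


def test_acf_constant_is_invalid():
    out = acf_features(np.full(100, 2.0))
    assert all(np.isnan(v) for v in out.values())


def test_acf_recovers_ar1_coefficient():
    rng = np.random.default_rng(42)
    x = np.empty(2000)
    x[0] = 0.0
    for i in range(1, 2000):
        x[i] = 0.8 * x[i - 1] + rng.normal()
    assert 0.74 <= acf_features(x)["acf_lag1"] <= 0.86


def test_ami_lag0_equals_marginal_entropy(rng):
    x = rng.normal(size=2000)
    edges = np.quantile(x, np.linspace(0, 1, 9))
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    h, _ = np.histogram(x, edges)
    p = h / h.sum()
    ent = -np.sum(p[p > 0] * np.log(p[p > 0]))
    assert ami(x, 0, 8) == pytest.approx(ent, abs=1e-12)


def test_ami_iid_is_small_and_nonnegative(rng):
    x = rng.uniform(size=5000)
    v = ami(x, 1, 8)
    assert 0.0 <= v < 0.02
    out = ami_features(x, rng=np.random.default_rng(0))
    assert all(v >= 0 or np.isnan(v) for k, v in out.items() if k.startswith("ami_lag"))


# ------------------------------------------------------------------ spectral

def test_psd_sine_concentrated_at_tone():
    rate = 44100.0
    x = np.sin(2 * np.pi * 1000.0 * np.arange(8192) / rate)
    out = psd_summaries(x, rate, "welch", "hamming")
    binw = rate / 1024
    assert abs(out["psd_welch_hamming_median"] - 1000.0) <= binw
    assert out["psd_welch_hamming_iqr"] <= 2 * binw


def test_psd_white_noise_median_near_quarter_rate():
    rng = np.random.default_rng(3)
    rate = 10000.0
    x = rng.normal(size=16384)
    out = psd_summaries(x, rate, "welch", "hamming")
    assert abs(out["psd_welch_hamming_median"] - rate / 4) / (rate / 4) < 0.05


def test_psd_invalid_on_silence():
    out = psd_summaries(np.zeros(4096), 1000.0)
    assert all(np.isnan(v) for v in out.values())


# ------------------------------------------------------------------ symbolic

def transition_matrix_bruteforce(symbols, k):
    counts = np.zeros((k, k))
    for a, b in zip(symbols[:-1], symbols[1:]):
        counts[a, b] += 1
    rows = counts.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1
    return counts / rows


def test_alternating_transition_matrix():
    x = np.array([1.0, 2.0] * 50)
    tm = transition_matrix(symbolize(x, 2), 2)
    assert np.allclose(tm, [[0, 1], [1, 0]])
    assert np.trace(tm) == 0.0
    assert np.allclose(tm.sum(axis=1), 1.0, atol=1e-12)


def test_transition_rows_sum_to_one(rng):
    for _ in range(50):
        x = rng.normal(size=int(rng.integers(30, 64)))
        k = int(rng.integers(2, 5))
        s = symbolize(x, k)
        tm = transition_matrix(s, k)
        occupied = np.bincount(s[:-1], minlength=k) > 0
        assert np.allclose(tm[occupied].sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(tm, transition_matrix_bruteforce(s, k), atol=1e-10)


def test_word_entropy_iid_near_uniform(rng):
    x = rng.uniform(size=3000)
    out = symbolic_features(x, alphabet_sizes=(3,))
    assert abs(out["motif3_entropy"] - math.log(27)) / math.log(27) < 0.05


def test_symbolic_invalid_for_degenerate_alphabet():
    out = symbolic_features(np.tile([0.0, 1.0], 60), alphabet_sizes=(2, 5))
    assert np.isfinite(out["trans_k2_max_offdiag"])
    assert np.isnan(out["trans_k5_max_offdiag"])


# ---------------------------------------------------------- permutation entropy

def perm_entropy_bruteforce(x, m, tau=1):
    patterns = []
    for t in range(len(x) - (m - 1) * tau):
        window = [x[t + j * tau] for j in range(m)]
        order = tuple(sorted(range(m), key=lambda i: (window[i], i)))
        patterns.append(order)
    counts = Counter(patterns)
    n = len(patterns)
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def test_perm_entropy_ramp_is_zero():
    out = permutation_entropy(np.arange(100.0), m=3)
    assert out["perm_entropy_m3_scale1"] == 0.0


def test_perm_entropy_iid_near_log6(rng):
    x = rng.uniform(size=10000)
    v = permutation_entropy(x, m=3)["perm_entropy_m3_scale1"]
    assert abs(v - math.log(6)) / math.log(6) < 0.02


def test_perm_entropy_bounds_and_oracle(rng):
    for _ in range(50):
        x = rng.normal(size=int(rng.integers(20, 64)))
        v = permutation_entropy(x, m=3)["perm_entropy_m3_scale1"]
        assert 0.0 <= v <= math.log(6) + 1e-12
        assert v == pytest.approx(perm_entropy_bruteforce(list(x), 3), abs=1e-10)


def test_multiscale_perm_entropy_short_scale_invalid():
    out = permutation_entropy(np.random.default_rng(0).normal(size=12), m=3, scales=(1, 8))
    assert np.isfinite(out["perm_entropy_m3_scale1"])
    assert np.isnan(out["perm_entropy_m3_scale8"])


# ------------------------------------------------------------------ AR models

def _ar1(rng, phi=0.8, n=2000):
    x = np.empty(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal()
    return x


def test_ar1_coefficient_recovery():
    x = _ar1(np.random.default_rng(5))
    coef, s2 = fit_ar(x, 1)
    assert 0.76 <= coef[0] <= 0.84
    assert ar_features(x)["ar_phi1"] == pytest.approx(coef[0])


def test_sbc_selects_order_one():
    hits = 0
    for seed in range(100):
        x = _ar1(np.random.default_rng(1000 + seed), n=2000)
        if ar_features(x, orders=(1, 2, 3, 4))["ar_best_order_sbc"] == 1.0:
            hits += 1
    assert hits >= 95


def test_prediction_rmse_nondecreasing_in_horizon():
    worse = 0
    for seed in range(20):
        x = _ar1(np.random.default_rng(seed), n=1000)
        out = ar_features(x, orders=(1,), horizons=(1, 2, 5, 10))
        r = [out[f"ar_pred_rmse_h{h}"] for h in (1, 2, 5, 10)]
        if all(np.diff(r) >= -1e-9):
            worse += 1
    assert worse == 20


def test_ar_constant_series_invalid():
    out = ar_features(np.full(500, 1.0))
    assert np.isnan(out["ar_sbc_p1"])


# ----------------------------------------------------------- stationarity etc.

def test_mean_step_increases_spread_of_means(rng):
    x = rng.normal(size=4000)
    stepped = x.copy()
    stepped[2000:] += 3.0
    a = stationarity_features(x, rng=np.random.default_rng(1))
    b = stationarity_features(stepped, rng=np.random.default_rng(1))
    assert b["stat_spread_mean"] > a["stat_spread_mean"]


def test_stationarity_constant_spreads_zero():
    out = stationarity_features(np.zeros(1000), rng=np.random.default_rng(0))
    assert out["stat_spread_mean"] == 0.0
    assert out["stat_spread_sd"] == 0.0
    assert out["localglobal_mean"] == 0.0


def test_stationarity_window_validation(rng):
    with pytest.raises(ValueError):
        stationarity_features(rng.normal(size=100), window_fraction=2.0)


def test_iterated_differencing_of_ramp():
    out = iterated_preprocess_compare(np.arange(200.0))
    assert out["ppiter_sd_iter1"] == 0.0


def test_differenced_white_noise_acf():
    rng = np.random.default_rng(9)
    x = rng.normal(size=5000)
    d = np.diff(x)
    out = acf_features(d)
    assert abs(out["acf_lag1"] - (-0.5)) < 0.05
    traj = iterated_preprocess_compare(x)
    assert np.isfinite(traj["ppiter_slope_acf1"])


# ------------------------------------------------------------------- dynamics

def test_walker_fixed_point_on_constant():
    out = walker_features(np.full(100, 2.5), attraction=0.3)
    assert out["walker_a0.3_mean_diff"] == 0.0
    assert out["walker_a0.3_sign_asym"] == 0.0


def test_walker_identity_at_full_attraction(rng):
    x = rng.normal(size=200)
    from scipy.signal import lfilter  # noqa: F401  (documenting the equivalence)
    out = walker_features(x, attraction=1.0)
    # walker equals the input shifted one step; mean difference is the drift
    w = np.concatenate(([x[0]], x[:-1]))
    assert out["walker_a1_mean_diff"] == pytest.approx(np.mean(w - x), abs=1e-12)


def test_walker_lowpass_variance():
    x = np.sin(np.arange(2000) * 0.3)
    out = walker_features(x, attraction=0.1)
    assert out["walker_a0.1_var_ratio"] <= 1.0


def test_forecast_constant_series():
    out = forecast_features(np.full(300, 4.0))
    assert all(out[f"forecast_rmse_L{L}"] == 0.0 for L in (1, 2, 4, 8, 16))
    assert out["surprise_mean"] == 0.0


def test_forecast_period2_surprise_bounded():
    x = np.tile([0.0, 1.0], 200)
    out = forecast_features(x, memory=2)
    assert out["surprise_mean"] <= math.log(2) + 1e-12


def test_forecast_noise_rmse_decreasing_then_flat():
    """Averaged over seeds, longer mean-forecast windows cannot hurt on white
    noise (the forecast tends to the true mean)."""
    rng = np.random.default_rng(0)
    deltas = []
    for _ in range(50):
        x = rng.normal(size=600)
        out = forecast_features(x, train_windows=(1, 2, 4, 8, 16))
        deltas.append(out["forecast_rmse_L1"] - out["forecast_rmse_L16"])
    assert np.mean(deltas) > 0


def test_hrv_hand_values():
    out = diffstats_hrv(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), pnn_thresholds=(0.5,))
    assert out["pnn_0.5sd"] == 1.0
    assert diffstats_hrv(np.array([0.0, 2.0, 0.0, 2.0]))["rmssd"] == pytest.approx(2.0)
    const = diffstats_hrv(np.full(10, 3.0))
    assert const["rmssd"] == 0.0 and const["pnn_0.5sd"] == 0.0


# ----------------------------------------------------------------- preprocess

def test_bandpass_passband_and_stopband(sine_motif):
    out = preprocess_waveform(sine_motif, target_rms_db=-20.0)
    # passband tone barely attenuated: compare shapes via rms before scaling
    rate = sine_motif.rate_hz
    t = np.arange(int(1.0 * rate)) / rate
    from scipy.signal import butter, lfilter

    b, a = butter(1, [250, 8000], btype="bandpass", fs=rate)
    for freq, min_db, max_db in ((1000.0, 0.0, 1.0), (50.0, 12.0, 100.0)):
        y = lfilter(b, a, np.sin(2 * np.pi * freq * t))
        att = -20 * np.log10(np.sqrt(np.mean(y[2000:] ** 2)) / np.sqrt(0.5))
        assert min_db <= att <= max_db
    assert np.sqrt(np.mean(out.samples**2)) == pytest.approx(0.1, rel=1e-6)


def test_preprocess_rejects_bad_band(sine_motif):
    with pytest.raises(ValueError):
        preprocess_waveform(sine_motif, band_hz=(250.0, 20000.0))
    with pytest.raises(ValueError):
        preprocess_waveform(
            MotifWaveform(np.zeros(1000), 22050.0, "b", "courtship")
        )


def test_silence_gate_zeroes_gaps():
    rate = 22050.0
    t = np.arange(int(0.1 * rate)) / rate
    syl = np.sin(2 * np.pi * 2000.0 * t)
    x = np.concatenate([syl, np.full(int(0.05 * rate), 1e-4), syl])
    w = MotifWaveform(x, rate, "b", "courtship")
    out = preprocess_waveform(w, silence_gate=True)
    mid = out.samples[len(syl) + 300 : len(syl) + int(0.05 * rate) - 300]
    assert np.allclose(mid, 0.0)


# ------------------------------------------------------------------- baseline

def test_sap_baseline_pure_tone(sine_motif):
    out = baseline_spectral_features(sine_motif)
    assert abs(out["sap_mean_pitch"] - 1000.0) / 1000.0 < 0.02
    assert out["sap_wiener_mean"] < -5.0
    assert out["sap_am_mean"] < 1e-3 * np.sqrt(np.mean(sine_motif.samples**2))


def test_sap_baseline_white_noise(noise_motif):
    out = baseline_spectral_features(noise_motif)
    assert out["sap_wiener_mean"] > -1.0


def test_sap_baseline_too_short():
    w = MotifWaveform(np.ones(16), 22050.0, "b", "courtship")
    out = baseline_spectral_features(w)
    assert all(np.isnan(v) for v in out.values())
    assert len(out) == 12
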