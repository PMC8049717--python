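"""Approximate SAP-style 12-feature acoustic baseline.

Frame-based approximations of the classic song-analysis features (mean
frequency, Wiener entropy, pitch, pitch goodness, frequency and amplitude
modulation). These follow the published default framing (9.27 ms window,
1.36 ms hop) but use plain spectral/autocorrelation estimators, so they are
an explicitly approximate stand-in for the original Sound Analysis Pro
implementations, not a re-implementation of them.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..types import MotifWaveform

WINDOW_S = 0.00927
HOP_S = 0.00136
PITCH_BAND_HZ = (250.0, 8000.0)


def _frames(x: np.ndarray, rate_hz: float) -> np.ndarray:
    nwin = max(int(round(WINDOW_S * rate_hz)), 8)
    hop = max(int(round(HOP_S * rate_hz)), 1)
    if x.size < nwin:
        raise ValueError("motif shorter than one analysis frame")
    return sliding_window_view(x, nwin)[::hop]


def baseline_spectral_features(w: MotifWaveform) -> Dict[str, float]:
    """The 12 SAP-like features: mean pitch, mean amplitude, and the mean and
    variance of mean frequency, Wiener entropy, pitch goodness, FM and AM.

    Frames whose RMS falls below 5% of the maximum frame RMS (inter-syllable
    gaps) are excluded from the spectral summaries.
    """
    x = np.asarray(w.samples, dtype=float)
    fs = w.rate_hz
    names = [
        "sap_mean_pitch", "sap_mean_amplitude",
        "sap_meanfreq_mean", "sap_meanfreq_var",
        "sap_wiener_mean", "sap_wiener_var",
        "sap_goodness_mean", "sap_goodness_var",
        "sap_fm_mean", "sap_fm_var",
        "sap_am_mean", "sap_am_var",
    ]
    try:
        frames = _frames(x, fs)
    except ValueError:
        return {n: np.nan for n in names}
    nwin = frames.shape[1]
    win = np.hamming(nwin)
    # window-weighted RMS (Blackman for its low sidelobes): insensitive to
    # the fractional tone period per frame, so pure tones show no spurious AM
    bwin = np.blackman(nwin)
    rms = np.sqrt((frames**2 @ bwin) / bwin.sum())
    active = rms >= 0.05 * rms.max() if rms.max() > 0 else np.zeros(rms.size, bool)
    if active.sum() < 3:
        return {n: np.nan for n in names}

    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    power = spec.sum(axis=1)
    power[power == 0.0] = np.nan
    meanfreq = (spec * freqs).sum(axis=1) / power
    # Wiener entropy: log of geometric over arithmetic mean of the spectrum
    with np.errstate(divide="ignore", invalid="ignore"):
        logspec = np.log(np.where(spec > 0, spec, np.nan))
        wiener = np.nanmean(logspec, axis=1) - np.log(power / spec.shape[1])

    # pitch via the autocorrelation peak inside the pitch band
    fr = frames - frames.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * nwin - 1)))
    f = np.fft.rfft(fr, nfft, axis=1)
    ac = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :nwin]
    ac0 = ac[:, 0].copy()
    ac0[ac0 == 0.0] = np.nan
    acn = ac / ac0[:, None]
    lag_lo = max(int(np.floor(fs / PITCH_BAND_HZ[1])), 1)
    lag_hi = min(int(np.ceil(fs / PITCH_BAND_HZ[0])), nwin - 1)
    band = acn[:, lag_lo : lag_hi + 1]
    best = np.argmax(band, axis=1) + lag_lo
    pitch = fs / best
    goodness = band.max(axis=1)

    # modulation: frame-to-frame derivative magnitudes
    fm = np.abs(np.diff(meanfreq))
    am = np.abs(np.diff(rms))
    act_fm = active[:-1] & active[1:]

    a = active
    return {
        "sap_mean_pitch": float(np.nanmean(pitch[a])),
        "sap_mean_amplitude": float(np.mean(rms[a])),
        "sap_meanfreq_mean": float(np.nanmean(meanfreq[a])),
        "sap_meanfreq_var": float(np.nanvar(meanfreq[a])),
        "sap_wiener_mean": float(np.nanmean(wiener[a])),
        "sap_wiener_var": float(np.nanvar(wiener[a])),
        "sap_goodness_mean": float(np.nanmean(goodness[a])),
        "sap_goodness_var": float(np.nanvar(goodness[a])),
        "sap_fm_mean": float(np.mean(fm[act_fm])) if act_fm.any() else np.nan,
        "sap_fm_var": float(np.var(fm[act_fm])) if act_fm.any() else np.nan,
        "sap_am_mean": float(np.mean(am[act_fm])) if act_fm.any() else np.nan,
        "sap_am_var": float(np.var(am[act_fm])) if act_fm.any() else np.nan,
    }
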