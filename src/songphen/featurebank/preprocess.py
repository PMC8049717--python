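"""Stimulus-style waveform preprocessing.

Mirrors how the song stimuli themselves were conditioned: a 2-pole
Butterworth band-pass (250-8000 Hz by default, applied forward only), RMS
normalization, and optional silencing of inter-syllable gaps with cosine
ramps at segment edges.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Tuple

import numpy as np
from scipy import signal

from ..types import MotifWaveform


def amplitude_envelope(x: np.ndarray, rate_hz: float, win_ms: float = 10.0) -> np.ndarray:
    """Moving-RMS amplitude envelope with a window of ``win_ms``."""
    x = np.asarray(x, dtype=float)
    win = max(int(round(win_ms * 1e-3 * rate_hz)), 1)
    kernel = np.ones(win) / win
    return np.sqrt(np.convolve(x * x, kernel, mode="same"))


def preprocess_waveform(
    w: MotifWaveform,
    band_hz: Tuple[float, float] = (250.0, 8000.0),
    target_rms_db: float = -20.0,
    ramp_ms: float = 2.0,
    silence_gate: bool = False,
    gate_rel_threshold: float = 0.05,
) -> MotifWaveform:
    """Band-pass, RMS-normalize and optionally gate a motif waveform.

    ``target_rms_db`` is dB relative to unit amplitude (dBFS); the playback
    calibration of the original stimuli (73 dB SPL) has no digital
    counterpart, so a fixed digital RMS plays the same role. The filter is a
    2-pole Butterworth band-pass run forward only (causal, no phase-reversed
    second pass). With ``silence_gate``, samples whose moving-RMS envelope
    falls below ``gate_rel_threshold`` times the envelope maximum are zeroed,
    with raised-cosine ramps of ``ramp_ms`` at every segment edge.
    """
    lo, hi = band_hz
    nyq = w.rate_hz / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError("band corners must satisfy 0 < lo < hi < Nyquist")
    x = np.asarray(w.samples, dtype=float)
    if np.all(x == 0.0):
        raise ValueError("cannot preprocess an all-zero waveform")
    b, a = signal.butter(1, [lo, hi], btype="bandpass", fs=w.rate_hz)
    y = signal.lfilter(b, a, x)

    if silence_gate:
        env = amplitude_envelope(y, w.rate_hz)
        keep = env >= gate_rel_threshold * env.max()
        gate = keep.astype(float)
        n_ramp = max(int(round(ramp_ms * 1e-3 * w.rate_hz)), 1)
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n_ramp + 1) / n_ramp))
        edges = np.flatnonzero(np.diff(keep.astype(int)))
        for e in edges:
            if keep[e + 1]:  # onset: ramp up into the segment
                s = slice(e + 1, min(e + 1 + n_ramp, y.size))
                gate[s] = np.minimum(gate[s], ramp[: s.stop - s.start])
            else:  # offset: ramp down out of the segment
                s = slice(max(e + 1 - n_ramp, 0), e + 1)
                gate[s] = np.minimum(gate[s], ramp[::-1][: s.stop - s.start])
        y = y * gate

    rms = float(np.sqrt(np.mean(y**2)))
    if rms == 0.0:
        raise ValueError("waveform is silent after filtering/gating")
    y = y * (10.0 ** (target_rms_db / 20.0) / rms)
    return replace(w, samples=y)
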