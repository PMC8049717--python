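"""Synthetic zebra-finch motifs and 2AFC operant sessions.

The generator emulates the contrasts reported between courtship (directed)
and non-courtship (undirected) renditions of the same motif:

* courtship motifs carry a slightly raised fundamental frequency
  (``f0_context_shift``), so the spectral median sits higher;
* non-courtship motifs have a weaker harmonic-amplitude decay
  (``bandwidth_effect``), spreading power over more harmonics and widening
  the spectral interquartile range;
* non-courtship motifs are more time irreversible (``asym_effect``): the
  asymmetry parameter skews both the syllable attack/decay envelope (fast
  attack, slow decay) and the intra-period pulse shape. The pulse skew is
  applied through harmonic *phases* only, so it leaves the power spectrum
  untouched and the three effects stay separable.

Each bird has a fixed "syllable family" (per-slot fundamental, duration and
timbre multipliers) shared by all its renditions, so motifs are stereotyped
within a bird and distinct across birds. Per-rendition parameters are
jittered with coefficient of variation ``rendition_jitter_cv`` and white
Gaussian noise is added at ``noise_floor`` times the signal RMS.

Randomness is fully reproducible: every (seed, bird, context, rendition)
tuple hashes to its own stream, so adding birds or renditions never perturbs
existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import CONTEXTS, COURTSHIP, NONCOURTSHIP, PROBE, TRAINING, MotifWaveform, TrialRecord

__all__ = [
    "SynthConfig",
    "BehaviorConfig",
    "make_motif",
    "make_dataset",
    "make_behavior_sessions",
    "trials_to_frame",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic motif family generator."""

    n_birds: int = 17
    renditions_per_context: int = 30
    probe_renditions_per_context: int = 0
    rate_hz: float = 44100.0
    syllable_count: int = 4
    f0_base_hz: float = 480.0
    f0_spacing_hz: float = 25.0
    f0_context_shift: float = 0.05
    bandwidth_effect: float = 0.3
    asym_effect: float = 0.4
    base_asym: float = 0.6
    base_decay: float = 3.0
    rendition_jitter_cv: float = 0.3
    noise_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_birds", "renditions_per_context", "syllable_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.probe_renditions_per_context < 0:
            raise ValueError("probe_renditions_per_context must be >= 0")
        if not (self.rate_hz > 0):
            raise ValueError("rate_hz must be positive")
        for name in ("f0_context_shift", "bandwidth_effect", "asym_effect",
                     "rendition_jitter_cv", "noise_floor", "base_asym"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.f0_base_hz) or self.f0_base_hz <= 0:
            raise ValueError("f0_base_hz must be finite and positive")


def _stream(seed: int, bird: str, context: str = "", rendition: int = -1) -> np.random.Generator:
    """Derive an independent RNG stream by stable hashing of identifiers."""
    key = [int(seed) & 0x7FFFFFFF, zlib.crc32(bird.encode())]
    if context:
        key.append(CONTEXTS.index(context))
    if rendition >= 0:
        key.append(rendition)
    return np.random.default_rng(np.random.SeedSequence(key))


def _bird_family(config: SynthConfig, bird: str) -> Dict[str, np.ndarray]:
    """Per-bird syllable-family parameters, fixed across renditions."""
    rng = _stream(config.seed, bird)
    k = config.syllable_count
    return {
        "f0_mult": rng.uniform(0.85, 1.3, size=k),
        "dur_s": rng.uniform(0.06, 0.10, size=k),
        "gap_s": rng.uniform(0.02, 0.04, size=max(k - 1, 0)),
        "decay_mult": rng.uniform(0.85, 1.15, size=k),
    }


def bird_f0(config: SynthConfig, bird_index: int) -> float:
    return config.f0_base_hz + bird_index * config.f0_spacing_hz


def _syllable(
    f0: float,
    dur_s: float,
    decay: float,
    asym: float,
    rate_hz: float,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One harmonic-stack syllable with asymmetric pulse and envelope.

    The pulse skew is a linear-in-harmonic phase rotation (harmonic h is
    rotated by (h-1)*asym radians): at asym = 0 every harmonic is in cosine
    phase and each cycle is palindromic (time reversible); increasing asym
    skews the cycle shape monotonically while leaving the harmonic amplitude
    spectrum exactly unchanged. A breathy broadband component whose spectrum
    follows the same exp(-f/(f0*decay)) shape is mixed in at a fixed
    fraction of the syllable RMS: real syllables are not pure line spectra,
    and the broadband floor keeps spectral quantiles continuous.
    """
    n = max(int(round(dur_s * rate_hz)), 8)
    t = np.arange(n) / rate_hz
    n_harm = int(min(14, np.floor(0.45 * rate_hz / f0)))
    n_harm = max(n_harm, 1)
    h = np.arange(1, n_harm + 1)
    amps = np.exp(-h / decay)
    phases = (h - 1.0) * asym
    # micro-vibrato (15% depth, 25 Hz) broadens the harmonic lines
    depth, f_mod = 0.15, 25.0
    warped = t + depth / (2 * np.pi * f_mod) * np.sin(2 * np.pi * f_mod * t)
    wave = (
        amps[:, None]
        * np.cos(2 * np.pi * f0 * h[:, None] * warped[None, :] + phases[:, None])
    ).sum(axis=0)
    if rng is not None:
        BREATH_FRACTION = 0.15
        freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
        shape = np.exp(-freqs / (f0 * decay))
        breath = np.fft.irfft(np.fft.rfft(rng.normal(size=n)) * shape, n)
        b_rms = np.sqrt(np.mean(breath**2))
        if b_rms > 0:
            wave = wave + breath * (
                BREATH_FRACTION * np.sqrt(np.mean(wave**2)) / b_rms
            )
    # raised-cosine attack/decay envelope; attack fraction shrinks with asym
    attack_frac = max(0.5 - 0.3 * min(asym, 1.4), 0.08)
    na = max(int(round(attack_frac * n)), 2)
    env = np.empty(n)
    env[:na] = 0.5 * (1.0 - np.cos(np.pi * np.arange(na) / na))
    nd = n - na
    env[na:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(nd) / nd))
    return wave * env


def make_motif(
    config: SynthConfig,
    bird: str,
    context: str,
    rendition: int = 0,
    role: str = TRAINING,
    bird_index: Optional[int] = None,
) -> MotifWaveform:
    """Synthesize one motif rendition for a bird in a social context."""
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    if bird_index is None:
        bird_index = _bird_index_from_id(bird)
    fam = _bird_family(config, bird)
    rng = _stream(config.seed, bird, context, rendition)

    f0_b = bird_f0(config, bird_index)
    court = context == COURTSHIP
    f0_ctx = f0_b * (1.0 + config.f0_context_shift) if court else f0_b
    decay_ctx = config.base_decay if court else config.base_decay * (1.0 + config.bandwidth_effect)
    asym_ctx = config.base_asym if court else config.base_asym + config.asym_effect

    # Pulse/envelope asymmetry fluctuates across renditions at the full
    # configured cv; harmonic decay (spectral timbre) at 0.3 of it; the
    # fundamental frequency and timing are the most stereotyped song
    # parameters and get one fifth of it.
    cv = config.rendition_jitter_cv
    TIMING_CV_FRACTION = 0.2
    DECAY_CV_FRACTION = 0.3

    def jit(scale: float = 1.0) -> float:
        return float(rng.lognormal(0.0, cv * scale)) if cv > 0 else 1.0

    pieces: List[np.ndarray] = []
    for s in range(config.syllable_count):
        f0 = f0_ctx * fam["f0_mult"][s] * jit(TIMING_CV_FRACTION)
        dur = fam["dur_s"][s] * jit(TIMING_CV_FRACTION)
        decay = decay_ctx * fam["decay_mult"][s] * jit(DECAY_CV_FRACTION)
        asym = asym_ctx * jit()
        pieces.append(_syllable(f0, dur, decay, asym, config.rate_hz, rng))
        if s < config.syllable_count - 1:
            gap = fam["gap_s"][s] * jit(TIMING_CV_FRACTION)
            pieces.append(np.zeros(max(int(round(gap * config.rate_hz)), 1)))
    x = np.concatenate(pieces)
    sig_rms = float(np.sqrt(np.mean(x**2)))
    if sig_rms == 0.0:
        raise ValueError("degenerate configuration produced a silent motif")
    if config.noise_floor > 0:
        x = x + rng.normal(0.0, config.noise_floor * sig_rms, size=x.size)
    x /= np.max(np.abs(x))
    return MotifWaveform(
        samples=x,
        rate_hz=config.rate_hz,
        bird_id=bird,
        context=context,
        role=role,
        rendition_id=f"{'p' if role == PROBE else 'r'}{rendition:03d}",
    )


def _bird_id(index: int) -> str:
    return f"bird{index:02d}"


def _bird_index_from_id(bird: str) -> int:
    try:
        return int(bird.removeprefix("bird"))
    except ValueError:
        return zlib.crc32(bird.encode()) % 32


def make_dataset(config: SynthConfig) -> Tuple[List[MotifWaveform], pd.DataFrame]:
    """Generate one motif family per bird plus the true generative parameters.

    Returns equal rendition counts per context for every bird (training
    renditions, plus ``probe_renditions_per_context`` probe renditions when
    configured) and a ground-truth table with one row per motif for recovery
    tests.
    """
    if config.n_birds < 1:
        raise ValueError("cannot generate an empty dataset (n_birds >= 1)")
    motifs: List[MotifWaveform] = []
    rows = []
    for b in range(config.n_birds):
        bird = _bird_id(b)
        for context in CONTEXTS:
            court = context == COURTSHIP
            n_train = config.renditions_per_context
            n_probe = config.probe_renditions_per_context
            for r in range(n_train + n_probe):
                role = TRAINING if r < n_train else PROBE
                w = make_motif(config, bird, context, rendition=r, role=role, bird_index=b)
                motifs.append(w)
                rows.append(
                    {
                        "bird": bird,
                        "context": context,
                        "role": role,
                        "rendition": w.rendition_id,
                        "f0_hz": bird_f0(config, b) * (1.0 + config.f0_context_shift * court),
                        "decay": config.base_decay * (1.0 + config.bandwidth_effect * (not court)),
                        "asym": config.base_asym + config.asym_effect * (not court),
                        "n_samples": w.samples.size,
                    }
                )
    return motifs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2AFC operant sessions
# ---------------------------------------------------------------------------


@dataclass
class BehaviorConfig:
    """Parameters of the synthetic 2AFC operant-session generator.

    Daily accuracy follows a logistic learning curve from ``p_start`` to
    ``p_asymptote``; probe trials are interleaved at ``probe_rate`` and
    rewarded at ``reward_rate`` independent of the response (partial
    reinforcement); reaction times are lognormal, with incorrect responses
    slower than correct ones once past the inflection day.
    """

    days: int = 30
    trials_per_day: int = 500
    p_start: float = 0.5
    p_asymptote: float = 0.85
    inflection_day: float = 10.0
    slope: float = 1.0
    probe_rate: float = 0.15
    reward_rate: float = 0.85
    no_response_rate: float = 0.02
    n_stimuli_per_context: int = 20
    n_probe_stimuli_per_context: int = 6
    rt_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"correct": (-0.2, 0.35), "incorrect": (0.25, 0.35)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("cannot generate an empty session (days >= 1)")
        if self.trials_per_day < 1:
            raise ValueError("trials_per_day must be >= 1")
        if not (0.0 <= self.p_start <= self.p_asymptote <= 1.0):
            raise ValueError("need 0 <= p_start <= p_asymptote <= 1")
        if not (0.0 < self.probe_rate < 1.0):
            raise ValueError("probe_rate must be in (0, 1)")
        if not (0.0 < self.reward_rate <= 1.0):
            raise ValueError("reward_rate must be in (0, 1]")


def learning_curve(config: BehaviorConfig, day: np.ndarray) -> np.ndarray:
    """P(correct) on a given day under the logistic learning model."""
    day = np.asarray(day, dtype=float)
    return config.p_start + (config.p_asymptote - config.p_start) / (
        1.0 + np.exp(-config.slope * (day - config.inflection_day))
    )


def make_behavior_sessions(config: BehaviorConfig) -> List[TrialRecord]:
    """Simulate per-trial 2AFC records across days."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x2AFC]))
    train_stims = [(f"{c[0]}{i:02d}", c) for c in CONTEXTS for i in range(config.n_stimuli_per_context)]
    probe_stims = [(f"p{c[0]}{i:02d}", c) for c in CONTEXTS for i in range(config.n_probe_stimuli_per_context)]
    trials: List[TrialRecord] = []
    for day in range(1, config.days + 1):
        p_day = float(learning_curve(config, np.array(day)))
        for t in range(config.trials_per_day):
            probe = bool(rng.random() < config.probe_rate)
            stim, context = (probe_stims if probe else train_stims)[
                rng.integers(len(probe_stims) if probe else len(train_stims))
            ]
            if rng.random() < config.no_response_rate:
                trials.append(
                    TrialRecord(day, t, stim, context, probe, "none", None, False, np.nan)
                )
                continue
            correct = bool(rng.random() < p_day)
            target = "A" if context == COURTSHIP else "B"
            response = target if correct else ("B" if target == "A" else "A")
            if probe:
                rewarded = bool(rng.random() < config.reward_rate)
            else:
                rewarded = correct and bool(rng.random() < config.reward_rate)
            key = "incorrect" if (not correct and day > config.inflection_day) else "correct"
            mu, sigma = config.rt_params[key]
            rt = float(rng.lognormal(mu, sigma))
            trials.append(TrialRecord(day, t, stim, context, probe, response, correct, rewarded, rt))
    return trials


def trials_to_frame(trials: List[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records with the canonical CSV column order."""
    return pd.DataFrame(
        {
            "day": [t.day for t in trials],
            "trial": [t.trial for t in trials],
            "stimulus_id": [t.stimulus_id for t in trials],
            "context": [t.context for t in trials],
            "probe": [t.probe for t in trials],
            "response": [t.response for t in trials],
            "correct": [t.correct for t in trials],
            "rewarded": [t.rewarded for t in trials],
            "rt_s": [t.rt_s for t in trials],
            "reward_balanced": [t.reward_balanced for t in trials],
        }
    )
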