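"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

COURTSHIP = "courtship"
NONCOURTSHIP = "noncourtship"
CONTEXTS = (COURTSHIP, NONCOURTSHIP)

TRAINING = "training"
PROBE = "probe"


@dataclass
class MotifWaveform:
    """One song motif: audio samples plus identifying labels.

    ``samples`` are dimensionless amplitudes at ``rate_hz``. ``context`` is the
    social context the motif was produced in (courtship = directed at a female,
    non-courtship = sung alone); ``role`` marks whether the motif belongs to the
    operant training set or is a held-out probe stimulus.
    """

    samples: np.ndarray
    rate_hz: float
    bird_id: str
    context: str
    role: str = TRAINING
    rendition_id: str = "r000"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.rate_hz > 0):
            raise ValueError("rate_hz must be positive")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}")
        if self.role not in (TRAINING, PROBE):
            raise ValueError("role must be 'training' or 'probe'")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass
class TrialRecord:
    """A single two-alternative forced-choice trial.

    ``response`` is the perch the subject hopped on ('A', 'B') or 'none' if no
    response was made within the window; ``correct`` is undefined (None) for
    no-response trials. Probe trials are rewarded at a fixed rate regardless of
    the response and are never punished.
    """

    day: int
    trial: int
    stimulus_id: str
    context: str
    probe: bool
    response: str
    correct: Optional[bool]
    rewarded: bool
    rt_s: float
    reward_balanced: bool = True

    def __post_init__(self) -> None:
        if self.response not in ("A", "B", "none"):
            raise ValueError("response must be 'A', 'B' or 'none'")
        if self.response != "none" and not (self.rt_s > 0):
            raise ValueError("rt_s must be positive for responded trials")


@dataclass
class SessionSummary:
    """Per-day aggregate 2AFC performance over qualifying trials."""

    day: int
    n_responses: int
    pct_correct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_correct <= 100.0):
            raise ValueError("pct_correct must be in [0, 100]")
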