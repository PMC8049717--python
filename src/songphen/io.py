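"""File-format plumbing: WAV, TSV/CSV tables, YAML run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .synthgen import BehaviorConfig, SynthConfig
from .types import MotifWaveform, PROBE, TRAINING

BEHAVIOR_COLUMNS = [
    "day", "trial", "stimulus_id", "context", "probe",
    "response", "correct", "rewarded", "rt_s",
]


def motif_filename(w: MotifWaveform) -> str:
    return f"{w.bird_id}_{w.context}_{w.rendition_id}.wav"


def write_wav(w: MotifWaveform, path: Union[str, Path], pcm16: bool = False) -> None:
    """Write a motif as mono WAV (float32 by default, PCM16 on request)."""
    x = np.asarray(w.samples, dtype=np.float32)
    if pcm16:
        peak = np.max(np.abs(x))
        scaled = x / peak if peak > 0 else x
        wavfile.write(path, int(w.rate_hz), (scaled * 32767).astype(np.int16))
    else:
        wavfile.write(path, int(w.rate_hz), x)


def read_wav(
    path: Union[str, Path],
    bird_id: Optional[str] = None,
    context: Optional[str] = None,
    role: str = TRAINING,
    rendition_id: Optional[str] = None,
) -> MotifWaveform:
    """Read a mono WAV; labels default to parsing `<bird>_<context>_<rendition>.wav`."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648.0
    else:
        data = data.astype(float)
    stem = Path(path).stem
    if bird_id is None or context is None or rendition_id is None:
        parts = stem.split("_")
        if len(parts) < 3:
            raise ValueError(f"cannot parse labels from filename {stem!r}")
        bird_id = bird_id or parts[0]
        context = context or parts[1]
        rendition_id = rendition_id or parts[2]
        # probe renditions carry a 'p' prefix in the rendition field
        if rendition_id.startswith("p"):
            role = PROBE
    return MotifWaveform(data, float(rate), bird_id, context, role, rendition_id)


def write_behavior_csv(trials_frame: pd.DataFrame, path: Union[str, Path]) -> None:
    trials_frame.loc[:, BEHAVIOR_COLUMNS + ["reward_balanced"]].to_csv(path, index=False)


def read_behavior_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a behavior trial log, validating the schema column by column."""
    df = pd.read_csv(path)
    for col in BEHAVIOR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"behavior CSV is missing required column {col!r}")
    if "reward_balanced" not in df.columns:
        df["reward_balanced"] = True
    for col in ("probe", "rewarded", "reward_balanced"):
        df[col] = df[col].astype(bool)
    return df


@dataclass
class RunConfig:
    """Full pipeline configuration (YAML-serializable)."""

    schema_version: int = 1
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    synth: SynthConfig = field(default_factory=SynthConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    classify: Dict = field(
        default_factory=lambda: {
            "n_trees": 300, "k_folds": 10, "n_iterations": 10,
            "top_k": 50, "random_subset_iterations": 1000,
        }
    )


def _check_unknown(d: Dict, allowed: List[str], where: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_unknown(raw, ["schema_version", "seed", "output_dir", "log_level",
                         "synth", "behavior", "classify"], "config")
    cfg = RunConfig()
    for key in ("schema_version", "seed", "output_dir", "log_level"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "synth" in raw:
        _check_unknown(raw["synth"], list(asdict(SynthConfig()).keys()), "synth")
        cfg.synth = SynthConfig(**raw["synth"])
    if "behavior" in raw:
        allowed = list(asdict(BehaviorConfig()).keys())
        _check_unknown(raw["behavior"], allowed, "behavior")
        kwargs = dict(raw["behavior"])
        if "rt_params" in kwargs:
            kwargs["rt_params"] = {k: tuple(v) for k, v in kwargs["rt_params"].items()}
        cfg.behavior = BehaviorConfig(**kwargs)
    if "classify" in raw:
        _check_unknown(raw["classify"], list(RunConfig().classify.keys()), "classify")
        cfg.classify.update(raw["classify"])
    return cfg


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    d = {
        "schema_version": cfg.schema_version,
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
        "synth": asdict(cfg.synth),
        "behavior": {
            **asdict(cfg.behavior),
            "rt_params": {k: list(v) for k, v in cfg.behavior.rt_params.items()},
        },
        "classify": dict(cfg.classify),
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def write_manifest(path: Union[str, Path], payload: Dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
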