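"""Feature registry and per-motif extraction driver.

A :class:`FeatureSpec` names one operation with one parameter set and lists
the scalar features it emits. ``extract_all`` runs a registry over a motif,
collecting every declared feature exactly once — as a number or as an
invalid marker (NaN) when the operation cannot be computed on that input —
so downstream matrix assembly can filter rather than crash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from ..types import MotifWaveform
from .armodel import ar_features
from .correlation import acf_features, ami_features
from .dynamics import diffstats_hrv, forecast_features, walker_features
from .irreversibility import co_trev_features, dk_trev_features
from .sap import baseline_spectral_features
from .spectral import psd_summaries_all
from .stationarity import iterated_preprocess_compare, stationarity_features
from .symbolic import permutation_entropy, symbolic_features

log = logging.getLogger(__name__)

# Adapter signature: (waveform, rng, **params) -> {feature name: value}
_OPERATIONS: Dict[str, Callable] = {
    "co_trev": lambda w, rng, **p: co_trev_features(w.samples, **p),
    "dk_trev": lambda w, rng, **p: dk_trev_features(w.samples, **p),
    "acf": lambda w, rng, **p: acf_features(w.samples, **p),
    "ami": lambda w, rng, **p: ami_features(w.samples, rng=rng, **p),
    "psd_summaries": lambda w, rng, **p: psd_summaries_all(w.samples, w.rate_hz, **p),
    "symbolic": lambda w, rng, **p: symbolic_features(w.samples, **p),
    "perm_entropy": lambda w, rng, **p: permutation_entropy(w.samples, **p),
    "ar": lambda w, rng, **p: ar_features(w.samples, **p),
    "stationarity": lambda w, rng, **p: stationarity_features(w.samples, rng=rng, **p),
    "pp_iterate": lambda w, rng, **p: iterated_preprocess_compare(w.samples, w.rate_hz, **p),
    "walker": lambda w, rng, **p: walker_features(w.samples, **p),
    "forecast": lambda w, rng, **p: forecast_features(w.samples, **p),
    "hrv": lambda w, rng, **p: diffstats_hrv(w.samples, **p),
    "sap_baseline": lambda w, rng, **p: baseline_spectral_features(w),
}


@dataclass(frozen=True)
class FeatureSpec:
    """One operation at one parameter set, with its declared output names."""

    operation_name: str
    parameters: Dict = field(default_factory=dict)
    output_feature_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.operation_name not in _OPERATIONS:
            raise ValueError(f"unknown operation {self.operation_name!r}")
        json.dumps(self.parameters)  # parameters must be serializable


@dataclass
class FeatureVector:
    """One motif's named feature values (NaN marks an invalid feature)."""

    bird_id: str
    context: str
    role: str
    rendition_id: str
    values: Dict[str, float]


def _probe_waveform() -> MotifWaveform:
    rng = np.random.default_rng(12345)
    x = rng.normal(size=4096) + np.sin(np.arange(4096) * 0.3)
    return MotifWaveform(x, 22050.0, "probe_bird", "courtship")


def make_spec(operation_name: str, **parameters) -> FeatureSpec:
    """Build a FeatureSpec, harvesting output names on a probe series."""
    op = _OPERATIONS[operation_name]
    out = op(_probe_waveform(), np.random.default_rng(0), **parameters)
    return FeatureSpec(operation_name, dict(parameters), tuple(out.keys()))


def default_registry() -> List[FeatureSpec]:
    """The full time-series feature bank (without the SAP-style baseline)."""
    return [
        make_spec("co_trev", taus=(1, 2, 3, "acf_zero", "ami_min")),
        make_spec("dk_trev", taus=(1, 2, 3, 4)),
        make_spec("acf", max_lag=33, lags=(1, 2, 3, 5, 14, 33)),
        make_spec("ami", lags=(1, 2, 3), n_bins=8),
        make_spec("psd_summaries"),
        make_spec("symbolic", alphabet_sizes=(2, 3, 4, 5)),
        make_spec("perm_entropy", m=3, tau=1, scales=(1, 2, 3, 4, 5)),
        make_spec("ar", orders=(1, 2, 3, 4, 5, 6), horizons=(1, 2, 5, 10), n_segments=5),
        make_spec("stationarity", window_fraction=0.1, n_boot=100),
        make_spec("pp_iterate"),
        make_spec("walker", attraction=0.1),
        make_spec("walker", attraction=0.5),
        make_spec("forecast", train_windows=(1, 2, 4, 8, 16), memory=3),
        make_spec("hrv", pnn_thresholds=(0.25, 0.5, 1.0)),
    ]


def sap_registry() -> List[FeatureSpec]:
    """The 12-feature approximate SAP-style baseline as its own registry."""
    return [make_spec("sap_baseline")]


def registry_feature_names(registry: Sequence[FeatureSpec]) -> List[str]:
    names: List[str] = []
    for spec in registry:
        names.extend(spec.output_feature_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in registry")
    return names


def registry_hash(registry: Sequence[FeatureSpec]) -> str:
    payload = json.dumps(
        [
            [s.operation_name, s.parameters, list(s.output_feature_names)]
            for s in registry
        ],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def registry_to_yaml(registry: Sequence[FeatureSpec], path) -> None:
    """Serialize a registry (operation names + parameters) to YAML."""
    import yaml

    payload = [
        {"operation": s.operation_name, "parameters": _listify(s.parameters)}
        for s in registry
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def registry_from_yaml(path) -> List[FeatureSpec]:
    """Rebuild a registry from YAML, re-deriving the output feature names."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        make_spec(entry["operation"], **_tuplify(entry.get("parameters") or {}))
        for entry in payload
    ]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _tuplify(obj):
    # parameter sequences are tuples internally (hashable, order-significant)
    if isinstance(obj, dict):
        return {k: tuple(v) if isinstance(v, list) else v for k, v in obj.items()}
    return obj


def _spec_rng(seed: int, spec: FeatureSpec) -> np.random.Generator:
    tag = zlib.crc32(
        (spec.operation_name + json.dumps(spec.parameters, sort_keys=True)).encode()
    )
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def extract_all(
    w: MotifWaveform,
    registry: Optional[Sequence[FeatureSpec]] = None,
    seed: int = 0,
) -> FeatureVector:
    """Run every registered operation on one motif.

    Every declared feature name appears exactly once in the output; an
    operation that fails on this motif contributes NaNs for all its features
    (logged, not raised), so a single degenerate motif never aborts a run.
    Operations with internal randomness get a stream derived from ``seed``
    and the spec identity, so extraction is bit-reproducible.
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise ValueError("registry must be non-empty")
    registry_feature_names(registry)  # raises on duplicates
    values: Dict[str, float] = {}
    for spec in registry:
        op = _OPERATIONS[spec.operation_name]
        try:
            out = op(w, _spec_rng(seed, spec), **spec.parameters)
        except Exception:
            log.warning(
                "operation %s failed on %s/%s/%s",
                spec.operation_name, w.bird_id, w.context, w.rendition_id,
                exc_info=True,
            )
            out = {}
        for name in spec.output_feature_names:
            v = out.get(name, np.nan)
            values[name] = float(v) if v is not None else np.nan
    return FeatureVector(w.bird_id, w.context, w.role, w.rendition_id, values)
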