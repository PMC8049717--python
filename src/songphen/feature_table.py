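"""Feature-matrix assembly, filtering, and two-stage normalization.

The pipeline order is fixed: degenerate features are filtered, each column
is passed through an outlier-resistant sigmoidal transform, and — when
several birds are combined so the classifier separates social contexts
rather than individuals — columns are rescaled to [0, 1] after aggregation.
Both transforms are strictly monotone per column, so within-column rank
order is preserved throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .featurebank.registry import FeatureVector

log = logging.getLogger(__name__)

META_COLUMNS = ("bird", "context", "role", "rendition")


@dataclass
class FeatureMatrix:
    """Motifs x features with a metadata index and a normalization state.

    ``meta`` carries one row per motif (bird, context, role, rendition);
    ``values`` is the numeric grid with NaN as the invalid marker. ``state``
    tracks how far along the normalization pipeline the matrix is:
    raw -> sigmoid -> unit.
    """

    meta: pd.DataFrame
    values: pd.DataFrame
    state: str = "raw"
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in ("raw", "sigmoid", "unit"):
            raise ValueError("state must be raw, sigmoid or unit")
        if list(self.meta.columns) != list(META_COLUMNS):
            raise ValueError(f"meta must have columns {META_COLUMNS}")
        if len(self.meta) != len(self.values):
            raise ValueError("meta and values must have equal row counts")
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def n_motifs(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> List[str]:
        return list(self.values.columns)

    def select(self, features: Sequence[str]) -> "FeatureMatrix":
        return replace(self, values=self.values.loc[:, list(features)].copy())


def from_feature_vectors(vectors: Sequence[FeatureVector], provenance: Dict | None = None) -> FeatureMatrix:
    """Stack per-motif feature vectors into a raw matrix."""
    if not vectors:
        raise ValueError("no feature vectors to assemble")
    meta = pd.DataFrame(
        {
            "bird": [v.bird_id for v in vectors],
            "context": [v.context for v in vectors],
            "role": [v.role for v in vectors],
            "rendition": [v.rendition_id for v in vectors],
        }
    )
    values = pd.DataFrame([v.values for v in vectors])
    return FeatureMatrix(meta, values, "raw", dict(provenance or {}))


def filter_features(m: FeatureMatrix) -> Tuple[FeatureMatrix, List[str]]:
    """Drop features that were not consistently extracted.

    A feature column is dropped when it is constant, contains any invalid
    marker, or is non-finite anywhere — the retained set is the set of
    features extracted successfully for every motif.
    """
    vals = m.values
    finite = np.isfinite(vals.to_numpy()).all(axis=0)
    nonconst = vals.nunique(dropna=False).to_numpy() > 1
    keep = finite & nonconst
    dropped = [c for c, k in zip(vals.columns, keep) if not k]
    if not keep.any():
        raise ValueError("all feature columns were dropped by filtering")
    out = replace(m, values=vals.loc[:, keep].copy())
    if dropped:
        log.info("filtered out %d features: %s", len(dropped), dropped[:10])
    return out, dropped


def robust_sigmoid(m: FeatureMatrix) -> FeatureMatrix:
    """Outlier-resistant sigmoidal normalization, per feature column.

    v -> 1 / (1 + exp(-(v - median) / (1.35 * IQR))); the 1.35 factor makes
    the IQR match a Gaussian standard deviation, so the transform behaves
    like a z-score squashed into (0, 1) but is insensitive to outliers.
    Columns with zero IQR cannot be scaled and are dropped (logged).
    """
    vals = m.values
    med = vals.median(axis=0)
    iqr = vals.quantile(0.75, axis=0) - vals.quantile(0.25, axis=0)
    keep = iqr > 0
    if not keep.any():
        raise ValueError("no feature has positive IQR")
    dropped = [c for c, k in keep.items() if not k]
    if dropped:
        log.info("robust_sigmoid dropped %d zero-IQR features: %s", len(dropped), dropped[:10])
    v = vals.loc[:, keep]
    z = (v - med[keep]) / (1.35 * iqr[keep])
    out = 1.0 / (1.0 + np.exp(-z))
    return replace(m, values=out, state="sigmoid")


def unit_scale(m: FeatureMatrix) -> FeatureMatrix:
    """Min-max rescaling to [0, 1], per feature column.

    Applied after aggregating birds so the combined matrix spans the full
    unit interval; columns with max = min are dropped. Idempotent.
    """
    vals = m.values
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    keep = hi > lo
    if not keep.any():
        raise ValueError("no feature has a nonzero range")
    v = vals.loc[:, keep]
    out = (v - lo[keep]) / (hi[keep] - lo[keep])
    return replace(m, values=out, state="unit")


def normalize_pipeline(m: FeatureMatrix) -> FeatureMatrix:
    """filter -> robust sigmoid -> unit scale, for a single-bird matrix."""
    filtered, _ = filter_features(m)
    return unit_scale(robust_sigmoid(filtered))


def assemble_combined(per_bird: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Combine per-bird matrices for the cross-bird (combined) classifier.

    Each bird's matrix is filtered and sigmoid-normalized against its own
    medians and IQRs — centering every bird at 0.5 so the combined
    classifier separates social contexts, not individuals — then the rows
    are concatenated over the shared feature set and unit-scaled on the
    aggregate.
    """
    if not per_bird:
        raise ValueError("no matrices to combine")
    normed = []
    for m in per_bird:
        filtered, _ = filter_features(m)
        normed.append(robust_sigmoid(filtered))
    shared = set(normed[0].feature_names)
    for m in normed[1:]:
        shared &= set(m.feature_names)
    if not shared:
        raise ValueError("no features shared across birds after filtering")
    order = [c for c in normed[0].feature_names if c in shared]
    if any(len(shared) < len(m.feature_names) for m in normed):
        log.info("combining on the %d-feature intersection", len(shared))
    meta = pd.concat([m.meta for m in normed], ignore_index=True)
    vals = pd.concat([m.values.loc[:, order] for m in normed], ignore_index=True)
    combined = FeatureMatrix(meta, vals, "sigmoid", dict(per_bird[0].provenance))
    filtered, _ = filter_features(combined)
    return unit_scale(filtered)


def split_by_bird(m: FeatureMatrix) -> List[FeatureMatrix]:
    """Split a raw matrix into per-bird matrices (stable bird order)."""
    out = []
    for bird in pd.unique(m.meta["bird"]):
        mask = (m.meta["bird"] == bird).to_numpy()
        out.append(
            FeatureMatrix(
                m.meta.loc[mask].reset_index(drop=True),
                m.values.loc[mask].reset_index(drop=True),
                m.state,
                dict(m.provenance),
            )
        )
    return out


def to_tsv(m: FeatureMatrix, path) -> None:
    """Serialize as TSV: meta columns first, NaN as 'NA'."""
    df = pd.concat([m.meta, m.values], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path, state: str = "raw") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta = df.loc[:, list(META_COLUMNS)]
    values = df.drop(columns=list(META_COLUMNS))
    return FeatureMatrix(meta, values, state)
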