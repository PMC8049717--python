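"""End-to-end pipeline commands tying the stages together.

Each ``cmd_*`` function is one pipeline stage (simulate, extract features,
classify, analyze behavior). They are thin orchestrators over the library
modules, used by both the command-line interface and the analysis scripts;
every stage writes a manifest recording its seed and outputs so runs are
auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import behavior as bh
from . import classify as cl
from . import feature_table as ft
from .featurebank import (
    default_registry,
    extract_all,
    preprocess_waveform,
    registry_hash,
    sap_registry,
)
from .io import (
    RunConfig,
    motif_filename,
    read_behavior_csv,
    read_wav,
    write_behavior_csv,
    write_manifest,
    write_wav,
)
from .synthgen import make_behavior_sessions, make_dataset, trials_to_frame
from .types import PROBE, TRAINING

log = logging.getLogger(__name__)


def cmd_simulate(config: RunConfig, out_dir: Optional[Path] = None) -> Dict:
    """Generate motif WAVs, the ground-truth table, and a behavior CSV."""
    out = Path(out_dir or config.output_dir)
    wav_dir = out / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    motifs, truth = make_dataset(config.synth)
    files = []
    for w in motifs:
        fname = motif_filename(w)
        write_wav(w, wav_dir / fname)
        files.append(fname)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    trials = make_behavior_sessions(config.behavior)
    write_behavior_csv(trials_to_frame(trials), out / "behavior_trials.csv")
    manifest = {
        "seed": config.seed,
        "synth_seed": config.synth.seed,
        "behavior_seed": config.behavior.seed,
        "n_motifs": len(motifs),
        "n_trials": len(trials),
        "wav_files": files,
    }
    write_manifest(out / "simulate_manifest.json", manifest)
    return manifest


def extract_matrix(
    motifs: Sequence,
    registry=None,
    seed: int = 0,
    preprocess: bool = True,
) -> ft.FeatureMatrix:
    """Preprocess and run the feature bank over a list of motif waveforms."""
    registry = registry if registry is not None else default_registry()
    vectors = []
    for w in motifs:
        try:
            wp = preprocess_waveform(w) if preprocess else w
            vectors.append(extract_all(wp, registry, seed=seed))
        except Exception:
            log.warning("skipping motif %s/%s/%s", w.bird_id, w.context, w.rendition_id,
                        exc_info=True)
    if not vectors:
        raise ValueError("every motif failed extraction")
    return ft.from_feature_vectors(vectors, {"registry_hash": registry_hash(registry)})


def cmd_extract(config: RunConfig, wav_dir: Path, out_dir: Optional[Path] = None) -> Dict:
    """Extract the feature matrix from a directory of motif WAVs."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted(Path(wav_dir).glob("*.wav"))
    if not paths:
        raise ValueError(f"no WAV files in {wav_dir}")
    motifs = []
    skipped = []
    for p in paths:
        try:
            motifs.append(read_wav(p))
        except Exception:
            skipped.append(p.name)
            log.warning("unreadable WAV skipped: %s", p.name, exc_info=True)
    if not motifs:
        raise ValueError("all WAV files were unreadable")
    registry = default_registry()
    matrix = extract_matrix(motifs, registry, seed=config.seed)
    ft.to_tsv(matrix, out / "features_raw.tsv")
    manifest = {
        "seed": config.seed,
        "registry_hash": registry_hash(registry),
        "n_motifs": matrix.n_motifs,
        "n_features": len(matrix.feature_names),
        "skipped": skipped,
    }
    write_manifest(out / "extract_manifest.json", manifest)
    return manifest


def classify_matrix(
    raw: ft.FeatureMatrix,
    n_trees: int = 300,
    k_folds: int = 10,
    n_iterations: int = 10,
    top_k: int = 50,
    random_subset_iterations: int = 0,
    seed: int = 0,
) -> Dict:
    """Run the combined-classifier analysis on a raw (multi-bird) matrix.

    Probe-role motifs are held out of all cross-validation and training
    folds; after the combined model is trained on every training motif, the
    probes are scored separately and given signed confidence scores.
    Returns a dict of results keyed by analysis name.
    """
    train_mask = (raw.meta["role"] == TRAINING).to_numpy()
    per_bird = ft.split_by_bird(raw)
    combined = ft.assemble_combined(per_bird)
    tr_mask = (combined.meta["role"] == TRAINING).to_numpy()
    X_train = combined.values.loc[tr_mask]
    y_train = combined.meta.loc[tr_mask, "context"].to_numpy()

    out: Dict = {}
    cv = cl.kfold_cv(X_train, y_train, k=k_folds, n_iterations=n_iterations,
                     n_trees=n_trees, seed=seed)
    out["combined_cv"] = cv

    model = cl.train_bgdt(X_train, y_train, n_trees=n_trees, seed=seed)
    ranking = cl.importance_ranking(model)
    out["importance"] = ranking
    out["top_k_cv"] = cl.top_k_evaluation(
        X_train, y_train, ranking, k=top_k,
        n_iterations=n_iterations, n_trees=n_trees, seed=seed + 1,
    )
    if random_subset_iterations > 0:
        out["random_subset"] = cl.random_subset_benchmark(
            X_train, y_train, k=top_k, n_iterations=random_subset_iterations,
            n_trees=n_trees, seed=seed + 2,
            reference_accuracy=out["top_k_cv"].median_accuracy,
        )

    probe_mask = ~tr_mask
    if probe_mask.any():
        X_probe = combined.values.loc[probe_mask]
        scores = cl.predict_scores(model, X_probe)
        truth = combined.meta.loc[probe_mask, "context"].to_numpy()
        conf = cl.confidence_scores(scores, truth)
        out["probe_scores"] = pd.DataFrame(
            {
                "bird": combined.meta.loc[probe_mask, "bird"].to_numpy(),
                "context": truth,
                "rendition": combined.meta.loc[probe_mask, "rendition"].to_numpy(),
                "score": scores,
                "predicted": cl.scores_to_labels(scores),
                "confidence": [c.value for c in conf],
            }
        )
    return out


def cmd_classify(config: RunConfig, matrix_tsv: Path, out_dir: Optional[Path] = None,
                 per_bird_reports: bool = False) -> Dict:
    """Normalize a raw feature matrix and run the classification analyses."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = ft.read_tsv(matrix_tsv)
    if raw.meta["context"].nunique() < 2:
        raise ValueError("matrix contains a single class")
    cc = config.classify
    res = classify_matrix(
        raw, n_trees=cc["n_trees"], k_folds=cc["k_folds"],
        n_iterations=cc["n_iterations"], top_k=cc["top_k"],
        random_subset_iterations=cc.get("random_subset_iterations", 0),
        seed=config.seed,
    )
    res["combined_cv"].records.to_csv(out / "combined_cv_records.csv", index=False)
    res["importance"].to_csv(out / "importance.csv", index=False)
    summary = {
        "seed": config.seed,
        "combined_median_accuracy": res["combined_cv"].median_accuracy,
        "top_k_median_accuracy": res["top_k_cv"].median_accuracy,
        "confusion": res["combined_cv"].confusion.to_dict(),
    }
    if "random_subset" in res:
        summary["random_subset_max"] = res["random_subset"]["max"]
        summary["random_subset_all_below_reference"] = res["random_subset"].get(
            "all_below_reference"
        )
    if "probe_scores" in res:
        res["probe_scores"].to_csv(out / "probe_confidence.csv", index=False)

    if per_bird_reports:
        per_bird = {}
        for m in ft.split_by_bird(raw):
            bird = m.meta["bird"].iloc[0]
            tr = (m.meta["role"] == TRAINING).to_numpy()
            normed = ft.normalize_pipeline(
                ft.FeatureMatrix(m.meta.loc[tr].reset_index(drop=True),
                                 m.values.loc[tr].reset_index(drop=True), "raw")
            )
            cvb = cl.kfold_cv(normed.values, normed.meta["context"].to_numpy(),
                              k=cc["k_folds"], n_iterations=cc["n_iterations"],
                              n_trees=cc["n_trees"], seed=config.seed)
            per_bird[bird] = cvb.median_accuracy
        summary["per_bird_median_accuracy"] = per_bird
    write_manifest(out / "classify_summary.json", summary)
    return summary


def cmd_behave(config: RunConfig, trials_csv: Path, out_dir: Optional[Path] = None) -> Dict:
    """Run the operant-learning analysis on a behavior trial log."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = read_behavior_csv(trials_csv)
    assessment = bh.assess_learning(df)
    probe = bh.probe_performance(df)
    sessions = bh.summarize_sessions(df)
    pd.DataFrame(
        {"day": [s.day for s in sessions],
         "n_responses": [s.n_responses for s in sessions],
         "pct_correct": [s.pct_correct for s in sessions]}
    ).to_csv(out / "daily_summary.csv", index=False)
    payload = {
        "seed": config.seed,
        "learning": dataclasses.asdict(assessment),
        "probe": dataclasses.asdict(probe),
    }
    write_manifest(out / "learning_assessment.json", payload)
    return payload
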