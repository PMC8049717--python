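"""Bagged-decision-tree classification of motif social context.

An ensemble of bootstrap-trained decision trees (Gini splits, random
feature subsetting at each split) votes on whether a motif is a courtship
or non-courtship rendition; the fraction of courtship votes is the
ensemble score. The module provides repeated stratified 10-fold
cross-validation with median accuracy, impurity-based feature-importance
ranking, top-k and random-k feature-subset evaluations, and signed
confidence scores that can be regressed against subject behavior.

The tree machinery is scikit-learn's bagged forest
(``RandomForestClassifier`` with sqrt feature subsetting); everything above
it — voting, validation protocol, importance normalization, subset
benchmarks, confidence scoring — is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .feature_table import FeatureMatrix
from .types import COURTSHIP, NONCOURTSHIP

DEFAULT_N_TREES = 300


@dataclass
class BGDTModel:
    """A fitted bagged-decision-tree ensemble with its feature names."""

    forest: RandomForestClassifier
    feature_names: List[str]
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)

    @property
    def oob_accuracy(self) -> float:
        """Accuracy on out-of-bag rows (the rows each tree did not draw),
        usable as an internal test set. Requires training with oob=True."""
        if not getattr(self.forest, "oob_score", False):
            raise ValueError("train with oob=True to record out-of-bag scores")
        return float(self.forest.oob_score_)


@dataclass
class CVResult:
    """Cross-validation output: per-motif records and aggregate accuracy.

    ``records`` has one row per (motif, iteration) with the true and
    predicted labels, the ensemble score, and fold/iteration ids.
    ``confusion`` pools actual x predicted counts over all iterations with
    rows/columns ordered (courtship, noncourtship).
    """

    records: pd.DataFrame
    iteration_accuracy: List[float]
    median_accuracy: float
    confusion: pd.DataFrame


@dataclass
class ConfidenceScore:
    """Signed distance of the ensemble score from the 0.5 decision boundary:
    positive when the prediction was correct, negative when incorrect."""

    index: int
    value: float


def _as_xy(X: Union[FeatureMatrix, pd.DataFrame]) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, FeatureMatrix):
        return X.values.to_numpy(dtype=float), X.feature_names
    return X.to_numpy(dtype=float), list(X.columns)


def _encode(y: Sequence[str]) -> np.ndarray:
    arr = np.asarray(y)
    bad = set(arr) - {COURTSHIP, NONCOURTSHIP}
    if bad:
        raise ValueError(f"unknown labels: {bad}")
    return (arr == COURTSHIP).astype(int)


def train_bgdt(
    X: Union[FeatureMatrix, pd.DataFrame],
    y: Sequence[str],
    n_trees: int = DEFAULT_N_TREES,
    features_per_split: Union[int, str] = "sqrt",
    seed: int = 0,
    oob: bool = False,
) -> BGDTModel:
    """Train the bagged ensemble on labeled motifs.

    Each tree sees a bootstrap sample of the rows and considers a random
    subset of ``features_per_split`` features at every split (default
    sqrt of the feature count); out-of-bag rows are recoverable from the
    forest's per-tree random state.
    """
    mat, names = _as_xy(X)
    yy = _encode(y)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    counts = np.bincount(yy, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 motifs per class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=features_per_split,
        bootstrap=True,
        oob_score=oob,
        random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    forest.fit(mat, yy)
    return BGDTModel(forest, names, int(seed))


def predict_scores(model: BGDTModel, X: Union[FeatureMatrix, pd.DataFrame]) -> np.ndarray:
    """Fraction of trees voting courtship, per motif (in [0, 1])."""
    mat, names = _as_xy(X)
    if names != model.feature_names:
        missing = set(model.feature_names) - set(names)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)[:5]}")
        # tolerate column reordering
        df = pd.DataFrame(mat, columns=names)
        mat = df.loc[:, model.feature_names].to_numpy()
    votes = np.stack([est.predict(mat) for est in model.forest.estimators_])
    return votes.mean(axis=0)


def scores_to_labels(scores: np.ndarray) -> np.ndarray:
    """Courtship iff score > 0.5; an exact 0.5 tie goes to non-courtship."""
    return np.where(np.asarray(scores) > 0.5, COURTSHIP, NONCOURTSHIP)


def kfold_cv(
    X: Union[FeatureMatrix, pd.DataFrame],
    y: Sequence[str],
    k: int = 10,
    n_iterations: int = 10,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    Each iteration reshuffles the motifs, partitions them into k
    stratified folds, holds each fold out once, and scores held-out motifs
    by ensemble vote. Accuracy per iteration is the fraction of correct
    held-out predictions; the reported summary is the median over
    iterations.
    """
    mat, names = _as_xy(X)
    yy = _encode(y)
    labels = np.asarray(y)
    n = len(labels)
    if n < k:
        raise ValueError("need at least k motifs")
    rows = []
    accs = []
    conf = np.zeros((2, 2), dtype=int)
    for it in range(n_iterations):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed * 1009 + it) & 0x7FFFFFFF)
        correct = 0
        for fold, (tr, te) in enumerate(skf.split(mat, yy)):
            if len(np.unique(yy[tr])) < 2:
                raise ValueError("a training split lost a class; reduce k")
            model = train_bgdt(
                pd.DataFrame(mat[tr], columns=names), labels[tr],
                n_trees=n_trees, seed=seed * 7919 + it * 101 + fold,
            )
            sc = predict_scores(model, pd.DataFrame(mat[te], columns=names))
            pred = scores_to_labels(sc)
            correct += int((pred == labels[te]).sum())
            for idx, s, p in zip(te, sc, pred):
                rows.append(
                    {"motif": int(idx), "true": labels[idx], "predicted": p,
                     "score": float(s), "fold": fold + 1, "iteration": it + 1}
                )
                conf[int(labels[idx] == NONCOURTSHIP), int(p == NONCOURTSHIP)] += 1
        accs.append(correct / n)
    records = pd.DataFrame(rows)
    confusion = pd.DataFrame(
        conf,
        index=pd.Index([COURTSHIP, NONCOURTSHIP], name="actual"),
        columns=pd.Index([COURTSHIP, NONCOURTSHIP], name="predicted"),
    )
    return CVResult(records, accs, float(np.median(accs)), confusion)


def importance_ranking(model: BGDTModel) -> pd.DataFrame:
    """Features ordered by mean impurity-decrease importance, max scaled to 1.

    Ties are broken by feature name so the ranking is fully deterministic;
    features never used in any split have importance exactly 0.
    """
    imp = model.forest.feature_importances_
    top = imp.max()
    norm = imp / top if top > 0 else imp
    df = pd.DataFrame({"feature": model.feature_names, "importance": norm})
    df = df.sort_values(["importance", "feature"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


def top_k_evaluation(
    X: Union[FeatureMatrix, pd.DataFrame],
    y: Sequence[str],
    ranking: pd.DataFrame,
    k: int = 50,
    n_iterations: int = 10,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> CVResult:
    """Cross-validate using only the k highest-importance features."""
    if k < 1:
        raise ValueError("k must be >= 1")
    names = list(ranking["feature"][:k])
    if isinstance(X, FeatureMatrix):
        Xk = X.select(names)
    else:
        Xk = X.loc[:, names]
    return kfold_cv(Xk, y, n_iterations=n_iterations, n_trees=n_trees, seed=seed)


def random_subset_benchmark(
    X: Union[FeatureMatrix, pd.DataFrame],
    y: Sequence[str],
    k: int = 50,
    n_iterations: int = 1000,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    reference_accuracy: Optional[float] = None,
) -> Dict:
    """Monte-Carlo benchmark of random k-feature subsets.

    Each iteration draws k features uniformly without replacement and runs
    a single-shuffle 10-fold cross-validation. Returns the accuracy
    distribution and, when a reference (top-k) accuracy is supplied,
    whether every random subset stayed below it.
    """
    mat, names = _as_xy(X)
    df = pd.DataFrame(mat, columns=names)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    accs = []
    for it in range(n_iterations):
        cols = rng.choice(len(names), size=k, replace=False)
        sub = df.iloc[:, np.sort(cols)]
        res = kfold_cv(sub, y, n_iterations=1, n_trees=n_trees, seed=seed * 31 + it)
        accs.append(res.median_accuracy)
    accs_arr = np.asarray(accs)
    out = {"accuracies": accs_arr, "max": float(accs_arr.max()), "mean": float(accs_arr.mean())}
    if reference_accuracy is not None:
        out["all_below_reference"] = bool(accs_arr.max() < reference_accuracy)
    return out


def confidence_scores(scores: Sequence[float], truth: Sequence[str]) -> List[ConfidenceScore]:
    """Signed confidence: |score - 0.5|, positive iff the prediction is correct."""
    sc = np.asarray(scores, dtype=float)
    if np.any((sc < 0) | (sc > 1)):
        raise ValueError("scores must lie in [0, 1]")
    truth_arr = np.asarray(truth)
    pred = scores_to_labels(sc)
    mag = np.abs(sc - 0.5)
    sign = np.where(pred == truth_arr, 1.0, -1.0)
    return [ConfidenceScore(i, float(s * m)) for i, (s, m) in enumerate(zip(sign, mag))]


def classifier_vs_subject(
    conf: Sequence[ConfidenceScore], subject_pct_correct: Sequence[float]
) -> Dict[str, float]:
    """Regress per-stimulus subject accuracy on classifier confidence.

    Ordinary least squares of subject percent-correct (as a fraction) on the
    signed confidence score; returns the slope, Pearson r and its two-sided
    p value. This is the fixed-effects analogue of the subject-level
    mixed-model analysis (no per-subject random effects).
    """
    x = np.asarray([c.value for c in conf], dtype=float)
    yv = np.asarray(subject_pct_correct, dtype=float)
    if x.size != yv.size or x.size < 3:
        raise ValueError("need >= 3 paired stimuli")
    if np.std(x) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance makes the correlation undefined")
    fit = stats.linregress(x, yv)
    return {"slope": float(fit.slope), "r": float(fit.rvalue), "p": float(fit.pvalue),
            "intercept": float(fit.intercept), "n": int(x.size)}
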