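"""Bagged-decision-tree classification: contracts, recovery, null safety."""

import numpy as np
import pandas as pd
import pytest

from songphen import classify as cl

C, N = "courtship", "noncourtship"


def _gaussian_problem(rng, n=200, p=20, informative=1, effect=3.0):
    X = rng.normal(size=(n, p))
    y = np.array([C, N] * (n // 2))
    for j in range(informative):
        X[:, j] += np.where(y == C, effect, 0.0)
    cols = [f"f{j:03d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y


def test_separable_training_accuracy(rng):
    X, y = _gaussian_problem(rng, n=100, p=5, effect=10.0)
    model = cl.train_bgdt(X, y, n_trees=50, seed=1)
    scores = cl.predict_scores(model, X)
    assert (cl.scores_to_labels(scores) == y).all()
    assert np.all((scores >= 0) & (scores <= 1))


def test_determinism_given_seed(rng):
    X, y = _gaussian_problem(rng)
    m1 = cl.train_bgdt(X, y, n_trees=40, seed=7)
    m2 = cl.train_bgdt(X, y, n_trees=40, seed=7)
    probe = X.iloc[:30]
    assert np.array_equal(cl.predict_scores(m1, probe), cl.predict_scores(m2, probe))


def test_single_class_rejected(rng):
    X, _ = _gaussian_problem(rng, n=20)
    with pytest.raises(ValueError):
        cl.train_bgdt(X, [C] * 20, seed=0)


def test_tie_at_half_predicts_noncourtship():
    assert cl.scores_to_labels(np.array([0.5]))[0] == N
    assert cl.scores_to_labels(np.array([0.5001]))[0] == C


def test_kfold_partition_and_separable_accuracy(rng):
    X, y = _gaussian_problem(rng, n=120, p=8, effect=8.0)
    res = cl.kfold_cv(X, y, k=10, n_iterations=3, n_trees=60, seed=3)
    assert res.median_accuracy >= 0.99
    # each motif appears exactly once per iteration
    per_iter = res.records.groupby("iteration")["motif"].nunique()
    assert (per_iter == 120).all()
    assert len(res.records) == 3 * 120
    assert res.confusion.to_numpy().sum() == 3 * 120


def test_kfold_null_within_binomial_ci(rng):
    X, y = _gaussian_problem(rng, n=200, p=20, informative=0)
    res = cl.kfold_cv(X, y, k=10, n_iterations=3, n_trees=60, seed=5)
    half = 1.96 * np.sqrt(0.25 / 200)
    assert abs(res.median_accuracy - 0.5) <= half + 0.05


def test_importance_single_informative_feature_ranks_first():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(3000 + seed)
        X, y = _gaussian_problem(rng, n=400, p=201, informative=1, effect=3.0)
        model = cl.train_bgdt(X, y, n_trees=100, seed=seed)
        ranking = cl.importance_ranking(model)
        if ranking["feature"].iloc[0] == "f000":
            hits += 1
    assert hits >= 95


def test_importance_normalization_and_unused_features(rng):
    X, y = _gaussian_problem(rng, n=100, p=4, effect=10.0)
    X["constantish"] = 0.0  # never split on a constant column
    model = cl.train_bgdt(X, y, n_trees=50, seed=2)
    ranking = cl.importance_ranking(model)
    assert ranking["importance"].max() == pytest.approx(1.0)
    assert (ranking["importance"] >= 0).all()
    assert ranking.set_index("feature").loc["constantish", "importance"] == 0.0


def test_top_k_equals_full_when_k_is_all(rng):
    X, y = _gaussian_problem(rng, n=80, p=6, effect=4.0)
    model = cl.train_bgdt(X, y, n_trees=50, seed=4)
    ranking = cl.importance_ranking(model)
    full = cl.kfold_cv(X, y, n_iterations=2, n_trees=50, seed=9)
    topk = cl.top_k_evaluation(X, y, ranking, k=6, n_iterations=2, n_trees=50, seed=9)
    assert topk.median_accuracy == pytest.approx(full.median_accuracy)


def test_top_1_on_separable_single_feature(rng):
    X, y = _gaussian_problem(rng, n=100, p=10, informative=1, effect=8.0)
    model = cl.train_bgdt(X, y, n_trees=50, seed=1)
    ranking = cl.importance_ranking(model)
    res = cl.top_k_evaluation(X, y, ranking, k=1, n_iterations=2, n_trees=50, seed=2)
    assert res.median_accuracy >= 0.9


def test_random_subset_null_centers_on_chance(rng):
    X, y = _gaussian_problem(rng, n=100, p=30, informative=0)
    out = cl.random_subset_benchmark(X, y, k=10, n_iterations=10, n_trees=40, seed=6)
    assert len(out["accuracies"]) == 10
    assert abs(out["mean"] - 0.5) < 0.12


def test_random_subsets_never_beat_top_k_in_sparse_regime():
    """With 10 strongly informative features in a large noise bank, the top-k
    subset holds all the signal and random draws rarely see any of it."""
    rng = np.random.default_rng(77)
    X, y = _gaussian_problem(rng, n=150, p=500, informative=10, effect=2.0)
    model = cl.train_bgdt(X, y, n_trees=100, seed=1)
    ranking = cl.importance_ranking(model)
    top = cl.top_k_evaluation(X, y, ranking, k=50, n_iterations=3, n_trees=100, seed=2)
    out = cl.random_subset_benchmark(
        X, y, k=50, n_iterations=30, n_trees=100, seed=3,
        reference_accuracy=top.median_accuracy,
    )
    assert out["all_below_reference"]


@pytest.mark.parametrize(
    "score, truth, expected",
    [(0.9, C, +0.4), (0.2, C, -0.3), (0.5, C, 0.0), (0.1, N, +0.4)],
)
def test_confidence_score_arithmetic(score, truth, expected):
    out = cl.confidence_scores([score], [truth])
    assert out[0].value == pytest.approx(expected, abs=1e-12)


def test_confidence_sign_matches_correctness(rng):
    scores = rng.uniform(size=200)
    truth = rng.choice([C, N], size=200)
    conf = cl.confidence_scores(scores, truth)
    pred = cl.scores_to_labels(scores)
    for c, p, t in zip(conf, pred, truth):
        if c.value != 0:
            assert (c.value > 0) == (p == t)
        assert abs(c.value) == pytest.approx(abs(scores[c.index] - 0.5))


def test_confidence_rejects_out_of_range():
    with pytest.raises(ValueError):
        cl.confidence_scores([1.2], [C])


def test_classifier_vs_subject_recovers_slope(rng):
    conf = [cl.ConfidenceScore(i, v) for i, v in enumerate(rng.uniform(-0.5, 0.5, 100))]
    subject = 0.5 + 0.8 * np.array([c.value for c in conf]) + rng.normal(0, 0.02, 100)
    out = cl.classifier_vs_subject(conf, subject)
    assert 0.6 <= out["slope"] <= 1.0
    assert out["r"] > 0.9


def test_classifier_vs_subject_perfect_line():
    conf = [cl.ConfidenceScore(i, v) for i, v in enumerate(np.linspace(-0.4, 0.4, 10))]
    subject = 0.5 + 0.5 * np.linspace(-0.4, 0.4, 10)
    out = cl.classifier_vs_subject(conf, subject)
    assert out["r"] == pytest.approx(1.0, abs=1e-12)


def test_classifier_vs_subject_null_is_flat(rng):
    ps = []
    for seed in range(50):
        r = np.random.default_rng(seed)
        conf = [cl.ConfidenceScore(i, v) for i, v in enumerate(r.uniform(-0.5, 0.5, 40))]
        subject = r.uniform(0.3, 0.7, 40)
        ps.append(cl.classifier_vs_subject(conf, subject)["p"])
    assert np.mean(np.array(ps) < 0.05) < 0.2
    with pytest.raises(ValueError):
        cl.classifier_vs_subject(
            [cl.ConfidenceScore(0, 0.1)] * 3, [0.5, 0.5, 0.5]
        )


def test_oob_accuracy_on_separable_data():
    rng = np.random.default_rng(11)
    X, y = _gaussian_problem(rng, n=200, p=10, informative=3, effect=3.0)
    model = cl.train_bgdt(X, y, n_trees=200, seed=4, oob=True)
    assert model.oob_accuracy >= 0.95
    plain = cl.train_bgdt(X, y, n_trees=20, seed=4)
    with pytest.raises(ValueError):
        _ = plain.oob_accuracy
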