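"""Operant-learning criterion, probe generalization, subject correlations."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from songphen import behavior as bh
from songphen.synthgen import BehaviorConfig, make_behavior_sessions, trials_to_frame
from songphen.types import SessionSummary, TrialRecord


def _trial(day, correct, probe=False, balanced=True, response="A", context="courtship"):
    return TrialRecord(day, 0, "s00", context, probe, response,
                       correct if response != "none" else None,
                       bool(correct), 0.5 if response != "none" else np.nan,
                       reward_balanced=balanced)


# --------------------------------------------------------------- sessions

def test_day_with_19_responses_excluded():
    trials = [_trial(1, True) for _ in range(19)] + [_trial(2, True) for _ in range(20)]
    out = bh.summarize_sessions(trials)
    assert [s.day for s in out] == [2]


def test_unbalanced_reward_day_excluded():
    # one unbalanced trial poisons the whole day
    trials = [_trial(1, True, balanced=(i > 0)) for i in range(30)]
    trials += [_trial(2, True) for _ in range(30)]
    out = bh.summarize_sessions(trials)
    assert [s.day for s in out] == [2]


def test_percent_correct_arithmetic():
    trials = [_trial(1, i < 10) for i in range(20)]
    out = bh.summarize_sessions(trials)
    assert out[0].pct_correct == 50.0
    assert out[0].n_responses == 20


def test_probe_and_no_response_trials_do_not_count():
    trials = [_trial(1, True) for _ in range(20)]
    trials += [_trial(1, False, probe=True) for _ in range(10)]
    trials += [_trial(1, False, response="none") for _ in range(5)]
    out = bh.summarize_sessions(trials)
    assert out[0].n_responses == 20
    assert out[0].pct_correct == 100.0


# ----------------------------------------------------------- sigmoid fit

def _sessions_from_curve(days, L, U, d0, s):
    pct = L + (U - L) / (1 + np.exp(-s * (np.arange(1, days + 1) - d0)))
    return [SessionSummary(d + 1, 500, float(p)) for d, p in enumerate(pct)]


def test_noiseless_sigmoid_recovery():
    sessions = _sessions_from_curve(30, 50.0, 85.0, 10.0, 1.0)
    fit, note = bh.fit_learning_sigmoid(sessions)
    assert fit is not None
    assert fit["U"] == pytest.approx(85.0, abs=1e-3)
    assert fit["threshold"] <= fit["U"]


def test_fit_requires_five_days():
    fit, note = bh.fit_learning_sigmoid(_sessions_from_curve(4, 50, 85, 2, 1))
    assert fit is None and "5" in note


@lru_cache(maxsize=None)
def _learner_frame(seed=123):
    cfg = BehaviorConfig(days=30, trials_per_day=500, p_start=0.5,
                         p_asymptote=0.85, inflection_day=10.0, slope=1.0, seed=seed)
    return trials_to_frame(make_behavior_sessions(cfg))


def test_learner_asymptote_recovered():
    a = bh.assess_learning(_learner_frame())
    assert a.converged
    assert 82.0 <= a.upper_asymptote <= 88.0


def test_learner_learning_day_in_range():
    a = bh.assess_learning(_learner_frame())
    assert a.learned
    assert 8 <= a.learning_day <= 15


def test_flat_performer_not_learned():
    cfg = BehaviorConfig(days=30, trials_per_day=500, p_start=0.5,
                         p_asymptote=0.5, seed=77)
    a = bh.assess_learning(trials_to_frame(make_behavior_sessions(cfg)))
    assert not a.learned


# ------------------------------------------------------- run-length rule

@pytest.mark.parametrize(
    "n_days, p, expected",
    [(32, 0.5, 10), (10, 0.1, 3)],
)
def test_required_run_length_arithmetic(n_days, p, expected):
    assert bh.required_run_length(n_days, p) == expected


def test_required_run_length_degenerate():
    assert bh.required_run_length(10, 0.0) == 1
    assert bh.required_run_length(10, 1.0) is None


def test_required_run_length_monotone():
    prev = 0
    for p in (0.1, 0.3, 0.5, 0.7, 0.9):
        r = bh.required_run_length(25, p)
        assert r >= prev
        prev = r
    assert bh.required_run_length(50, 0.5) >= bh.required_run_length(10, 0.5)


def _prob_run_at_least(n, r, p):
    """Exact DP for P(some run of >= r successes in n Bernoulli(p) trials)."""
    # state: current run length capped at r; absorbing at r
    probs = np.zeros(r + 1)
    probs[0] = 1.0
    for _ in range(n):
        new = np.zeros(r + 1)
        new[r] = probs[r]
        for run in range(r):
            new[min(run + 1, r)] += probs[run] * p
            new[0] += probs[run] * (1 - p)
        probs = new
    return probs[r]


def test_run_length_conservative_vs_exact_dp():
    """The expected-count rule never demands a shorter run than the exact
    run-occurrence probability calculation at the same alpha."""
    for n in (5, 10, 20):
        for p in (0.2, 0.4, 0.5, 0.6, 0.8):
            r_bound = bh.required_run_length(n, p)
            r_exact = 1
            while _prob_run_at_least(n, r_exact, p) >= 0.05:
                r_exact += 1
                if r_exact > n:
                    break
            assert r_bound >= r_exact


def test_detect_learning_day_boundary_cases():
    sessions = [SessionSummary(d, 100, 90.0) for d in range(1, 11)]
    assert bh.detect_learning_day(sessions, 80.0, 3) == 1
    mixed = [SessionSummary(d, 100, 90.0 if d >= 4 else 50.0) for d in range(1, 11)]
    assert bh.detect_learning_day(mixed, 80.0, 3) == 4
    assert bh.detect_learning_day(mixed, 95.0, 2) is None


# ----------------------------------------------------------------- probes

def test_probes_perfect_generalization():
    trials = []
    for day in range(1, 11):
        for ctx in ("courtship", "noncourtship"):
            trials += [_trial(day, True, probe=True, context=ctx) for _ in range(10)]
    rep = bh.probe_performance(trials)
    assert rep.generalized
    assert rep.pct_correct["courtship"] == 100.0
    assert rep.n_probes == {"courtship": 100, "noncourtship": 100}


def test_probe_chance_rarely_generalizes():
    false_alarms = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        trials = []
        for day in range(1, 9):
            for ctx in ("courtship", "noncourtship"):
                trials += [
                    _trial(day, bool(rng.random() < 0.5), probe=True, context=ctx)
                    for _ in range(12)
                ]
        if bh.probe_performance(trials).generalized:
            false_alarms += 1
    assert false_alarms <= 10


def test_missing_probe_context_blocks_generalization():
    trials = [_trial(d, True, probe=True) for d in range(1, 6) for _ in range(10)]
    rep = bh.probe_performance(trials)
    assert not rep.generalized


def test_probe_counts_match_responded_probes():
    trials = [_trial(1, True, probe=True) for _ in range(7)]
    trials += [TrialRecord(1, 0, "s", "courtship", True, "none", None, False,
                           np.nan)]
    rep = bh.probe_performance(trials)
    assert rep.n_probes["courtship"] == 7


# ----------------------------------------------------- subject correlations

def test_identical_subjects_correlate_perfectly(rng):
    acc = rng.uniform(0.5, 1.0, size=20)
    table = pd.DataFrame([acc, acc], index=["f1", "f2"])
    out = bh.pairwise_subject_correlations(table)
    assert out["r"].loc["f1", "f2"] == pytest.approx(1.0)
    assert out["r"].equals(out["r"].T)
    assert np.allclose(np.diag(out["r"]), 1.0)


def test_independent_subjects_significance_near_alpha():
    sig = 0
    trials = 200
    for seed in range(trials):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(rng.uniform(0.4, 1.0, size=(2, 30)), index=["a", "b"])
        out = bh.pairwise_subject_correlations(table)
        sig += out["n_significant_positive"]
    # one-sided significant-positive fraction under the null ~ alpha/2
    assert sig / trials < 0.08


def test_zero_variance_subject_skipped():
    table = pd.DataFrame(
        [[0.5] * 10, list(np.linspace(0.4, 0.9, 10))], index=["flat", "var"]
    )
    out = bh.pairwise_subject_correlations(table)
    assert np.isnan(out["r"].loc["flat", "var"])
    assert out["n_tests"] == 0
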