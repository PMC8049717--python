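"""Analysis of 2AFC operant sessions: learning criterion and generalization.

Learning is declared from daily percent-correct trajectories in three
steps: (1) fit a four-parameter logistic (sigmoid) learning curve across
all qualifying days; (2) take the lower 95% confidence bound of the upper
asymptote as the performance threshold and estimate the probability of a
day exceeding it; (3) use a geometric run-length argument to find how many
consecutive supra-threshold days are needed before such a run is unlikely
to be chance, and scan for the first day starting such a run. Probe trials
— novel stimuli interleaved at a low rate and rewarded at a fixed rate
regardless of response — test whether the learned classification
generalizes beyond the memorized training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import SessionSummary, TrialRecord

MIN_RESPONSES_PER_DAY = 20


def _as_frame(trials: Union[Sequence[TrialRecord], pd.DataFrame]) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    from .synthgen import trials_to_frame

    return trials_to_frame(list(trials))


@dataclass
class LearningAssessment:
    """Outcome of the sigmoid + run-length learning criterion."""

    converged: bool
    lower_asymptote: float = np.nan
    upper_asymptote: float = np.nan
    inflection_day: float = np.nan
    slope: float = np.nan
    threshold: float = np.nan  # lower 95% CI bound of the upper asymptote
    p_above: float = np.nan
    required_run: Optional[int] = None
    learning_day: Optional[int] = None
    n_days: int = 0
    notes: str = ""

    @property
    def learned(self) -> bool:
        return self.learning_day is not None


def summarize_sessions(
    trials: Union[Sequence[TrialRecord], pd.DataFrame]
) -> List[SessionSummary]:
    """Daily percent correct over responded, reward-balanced training trials.

    Days with fewer than ``MIN_RESPONSES_PER_DAY`` responses and days on
    which the two response perches were rewarded at different rates are
    excluded; probe and no-response trials never enter the percentages.
    """
    df = _as_frame(trials)
    # a day on which the two perches were rewarded unequally is excluded whole
    balanced_days = df.groupby("day")["reward_balanced"].transform("all")
    ok = (df["response"] != "none") & ~df["probe"].astype(bool) & balanced_days
    df = df.loc[ok]
    out: List[SessionSummary] = []
    for day, grp in df.groupby("day", sort=True):
        n = len(grp)
        if n < MIN_RESPONSES_PER_DAY:
            continue
        pct = 100.0 * grp["correct"].astype(bool).mean()
        out.append(SessionSummary(int(day), int(n), float(pct)))
    return out


def _sigmoid(day: np.ndarray, L: float, U: float, d0: float, s: float) -> np.ndarray:
    return L + (U - L) / (1.0 + np.exp(-s * (day - d0)))


def fit_learning_sigmoid(
    sessions: Sequence[SessionSummary],
) -> Tuple[Optional[Dict[str, float]], str]:
    """Least-squares 4-parameter logistic fit of daily percent correct.

    Returns (parameters, note). Parameters include the lower 95% confidence
    bound of the upper asymptote U ("threshold"), computed from the fit
    covariance with a t quantile on n - 4 degrees of freedom. On
    non-convergence returns (None, diagnostic) rather than raising, which
    downstream code treats as "not learned".
    """
    if len(sessions) < 5:
        return None, "fewer than 5 qualifying days"
    days = np.array([s.day for s in sessions], dtype=float)
    pct = np.array([s.pct_correct for s in sessions], dtype=float)
    p0 = (50.0, float(pct.max()), float(np.median(days)), 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _sigmoid, days, pct, p0=p0,
            bounds=([0.0, 0.0, days.min() - 50.0, 0.0], [100.0, 100.0, days.max() + 50.0, 20.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as e:
        return None, f"sigmoid fit failed: {e}"
    L, U, d0, s = (float(v) for v in popt)
    se_u = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    dof = max(len(sessions) - 4, 1)
    tcrit = float(stats.t.ppf(0.975, dof))
    threshold = U - tcrit * se_u
    if not np.isfinite(threshold):
        return None, "asymptote confidence interval is unbounded"
    return (
        {"L": L, "U": U, "d0": d0, "s": s, "se_U": se_u, "threshold": threshold},
        "",
    )


def required_run_length(n_days: int, p_above: float, alpha: float = 0.05) -> Optional[int]:
    """Consecutive supra-threshold days needed to look non-random.

    Uses the expected-count bound on chance runs: the smallest r with
    n_days * p_above**r < alpha. The bound is conservative (the expected
    number of length-r runs upper-bounds the probability of seeing one) and
    monotone in both arguments. Degenerate cases: p_above = 0 gives r = 1;
    p_above = 1 means no run length can ever look non-random (None).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not (0.0 <= p_above <= 1.0):
        raise ValueError("p_above must be a probability")
    if p_above == 0.0:
        return 1
    if p_above == 1.0:
        return None
    r = 1
    while n_days * p_above**r >= alpha:
        r += 1
        if r > 10_000:  # p_above extremely close to 1
            return None
    return r


def detect_learning_day(
    sessions: Sequence[SessionSummary], threshold: float, required_run: int
) -> Optional[int]:
    """First qualifying day starting >= required_run consecutive days above
    threshold (consecutive in the sequence of qualifying days)."""
    if required_run < 1:
        raise ValueError("required_run must be >= 1")
    above = [s.pct_correct > threshold for s in sessions]
    count = 0
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= required_run:
            return sessions[i - required_run + 1].day
    return None


def chance_p_above(sessions: Sequence[SessionSummary], threshold: float) -> float:
    """Probability that a chance-level (p = 0.5) day exceeds the threshold.

    Uses a binomial day model at the median daily response count: the
    run-length criterion asks how often a run would arise if the bird were
    guessing, so the relevant per-day probability is the chance performer's.
    """
    n = int(np.median([s.n_responses for s in sessions]))
    k = int(np.floor(threshold / 100.0 * n))
    return float(np.clip(stats.binom.sf(k, n, 0.5), 1e-12, 1.0 - 1e-12))


def empirical_p_above(sessions: Sequence[SessionSummary], threshold: float) -> float:
    """Observed fraction of qualifying days above the threshold."""
    pct = np.array([s.pct_correct for s in sessions])
    return float(np.mean(pct > threshold))


def assess_learning(
    trials: Union[Sequence[TrialRecord], pd.DataFrame],
    alpha: float = 0.05,
    p_above_estimator: str = "chance",
) -> LearningAssessment:
    """Run the complete learning criterion on a trial log.

    ``p_above`` feeds the run-length rule and can be estimated two ways:
    ``"chance"`` (default) is the probability that a guessing bird's day
    would clear the threshold — the natural null for a criterion meant to
    make a run of supra-threshold days "appear non-random" — while
    ``"empirical"`` is the observed fraction of days above the threshold
    (more conservative: it inflates the required run when the bird sits
    near its own threshold after learning).
    """
    sessions = summarize_sessions(trials)
    if not sessions:
        return LearningAssessment(converged=False, notes="no qualifying days")
    fit, note = fit_learning_sigmoid(sessions)
    if fit is None:
        return LearningAssessment(converged=False, n_days=len(sessions), notes=note)
    if p_above_estimator == "chance":
        p_above = chance_p_above(sessions, fit["threshold"])
    elif p_above_estimator == "empirical":
        p_above = empirical_p_above(sessions, fit["threshold"])
    else:
        raise ValueError("p_above_estimator must be 'chance' or 'empirical'")
    r = required_run_length(len(sessions), p_above, alpha)
    day = detect_learning_day(sessions, fit["threshold"], r) if r is not None else None
    return LearningAssessment(
        converged=True,
        lower_asymptote=fit["L"],
        upper_asymptote=fit["U"],
        inflection_day=fit["d0"],
        slope=fit["s"],
        threshold=fit["threshold"],
        p_above=p_above,
        required_run=r,
        learning_day=day,
        n_days=len(sessions),
    )


@dataclass
class ProbeReport:
    """Probe-trial generalization summary."""

    pct_correct: Dict[str, float]
    p_values: Dict[str, float]
    above_chance: Dict[str, bool]
    generalized: bool
    n_probes: Dict[str, int]
    training_pct_correct: float
    probe_pct_correct: float
    first_day_pct: float
    last_day_pct: float
    median_rt: Dict[str, float] = field(default_factory=dict)


def probe_performance(
    trials: Union[Sequence[TrialRecord], pd.DataFrame], alpha: float = 0.05
) -> ProbeReport:
    """Per-context probe accuracy, above-chance tests, and generalization.

    Daily probe-correct proportions are the test units: a one-sample t test
    against 0.5 per context, with generalization requiring both contexts
    significantly above chance. A context with no responded probes is
    untestable and blocks generalization. Also reports probe-vs-training
    percent correct, first-vs-last probe day, and median reaction times.
    """
    df = _as_frame(trials)
    responded = df.loc[df["response"] != "none"].copy()
    responded["correct"] = responded["correct"].astype(bool)
    probes = responded.loc[responded["probe"].astype(bool)]
    train = responded.loc[~responded["probe"].astype(bool)]

    pct: Dict[str, float] = {}
    pvals: Dict[str, float] = {}
    above: Dict[str, bool] = {}
    n_probes: Dict[str, int] = {}
    for ctx, grp in probes.groupby("context"):
        n_probes[ctx] = len(grp)
        pct[ctx] = 100.0 * grp["correct"].mean()
        daily = grp.groupby("day")["correct"].mean()
        if len(daily) >= 2 and daily.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(daily, 0.5)
            pvals[ctx] = float(p)
            above[ctx] = bool(p < alpha and daily.mean() > 0.5)
        else:
            pvals[ctx] = np.nan
            above[ctx] = bool(len(daily) > 0 and daily.mean() == 1.0 and len(daily) >= 2)
    contexts_seen = set(probes["context"])
    generalized = bool(
        len(contexts_seen) == 2 and all(above.get(c, False) for c in contexts_seen)
    )

    by_day = probes.groupby("day")["correct"].mean()
    first_pct = 100.0 * float(by_day.iloc[0]) if len(by_day) else np.nan
    last_pct = 100.0 * float(by_day.iloc[-1]) if len(by_day) else np.nan
    return ProbeReport(
        pct_correct=pct,
        p_values=pvals,
        above_chance=above,
        generalized=generalized,
        n_probes=n_probes,
        training_pct_correct=100.0 * float(train["correct"].mean()) if len(train) else np.nan,
        probe_pct_correct=100.0 * float(probes["correct"].mean()) if len(probes) else np.nan,
        first_day_pct=first_pct,
        last_day_pct=last_pct,
        median_rt={
            "training": float(train["rt_s"].median()) if len(train) else np.nan,
            "probe": float(probes["rt_s"].median()) if len(probes) else np.nan,
        },
    )


def pairwise_subject_correlations(
    per_stimulus_accuracy: pd.DataFrame, alpha: float = 0.05
) -> Dict:
    """Pearson correlations of per-stimulus accuracy between all subject pairs.

    ``per_stimulus_accuracy`` is subjects x stimuli (percent or fraction
    correct; NaN where a subject was not tested on a stimulus). Pairs
    sharing fewer than 3 stimuli, or with zero variance on the shared set,
    are skipped (NaN in the matrices). Returns symmetric r and p matrices
    with unit diagonal and the count of significant positive pairs.
    """
    subs = list(per_stimulus_accuracy.index)
    n = len(subs)
    r = pd.DataFrame(np.eye(n), index=subs, columns=subs)
    p = pd.DataFrame(np.zeros((n, n)), index=subs, columns=subs)
    n_sig = 0
    n_tests = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = per_stimulus_accuracy.iloc[i]
            b = per_stimulus_accuracy.iloc[j]
            ok = a.notna() & b.notna()
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            rv, pv = stats.pearsonr(a[ok], b[ok])
            r.iloc[i, j] = r.iloc[j, i] = rv
            p.iloc[i, j] = p.iloc[j, i] = pv
            n_tests += 1
            if pv < alpha and rv > 0:
                n_sig += 1
    return {"r": r, "p": p, "n_significant_positive": n_sig, "n_tests": n_tests}
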