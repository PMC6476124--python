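"""Decision rule on predicted risk curves and class-survival comparison.

The at-risk decision rule mirrors clinical reading of the predicted
curves: a subject is flagged as a predicted failure when the upper 95%
confidence limit of the predicted failure probability exceeds 50% at any
time up to the horizon; a predicted survivor keeps the median below 30%
and the upper limit below 50% throughout.  The two conditions alone do
not partition the outcome space, so an explicit ``indeterminate``
category closes the gap; a binary reproduction mode (failure iff the
upper limit exceeds 50%) is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import Cohort, FitResult
from .prediction import RiskCurve, risk_curve_with_ci

PREDICTED_FAILURE = "predicted_failure"
PREDICTED_SURVIVAL = "predicted_survival"
INDETERMINATE = "indeterminate"


@dataclass
class DecisionRule:
    failure_threshold: float = 0.50
    safe_prob_threshold: float = 0.30
    horizon: float = 10.0
    binary: bool = False  # failure iff upper95 > failure_threshold, else survival

    def __post_init__(self) -> None:
        if not 0.0 < self.safe_prob_threshold < self.failure_threshold < 1.0:
            raise ValueError(
                "need 0 < safe_prob_threshold < failure_threshold < 1"
            )


def classify_curve(curve: RiskCurve, rule: DecisionRule | None = None) -> str:
    """Classify one predicted risk curve under the decision rule."""
    rule = rule or DecisionRule()
    mask = curve.grid <= rule.horizon + 1e-9
    if not mask.any():
        raise ValueError("curve does not reach into the decision horizon")
    upper = curve.upper95[mask]
    median = curve.median[mask]
    if np.any(upper > rule.failure_threshold):
        return PREDICTED_FAILURE
    if rule.binary:
        return PREDICTED_SURVIVAL
    if np.all(median < rule.safe_prob_threshold) and np.all(
        upper < rule.failure_threshold
    ):
        return PREDICTED_SURVIVAL
    return INDETERMINATE


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, and accuracy, as percentages."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one positive and one negative")
    total = tp + fn + tn + fp
    return {
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "accuracy": 100.0 * (tp + tn) / total,
    }


def kaplan_meier(
    times: Sequence[float], events: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimator with right censoring.

    Returns the distinct event times and the survival estimate just after
    each (a right-continuous step function; S = 1 before the first event).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    n = times.size
    S = 1.0
    out = []
    for t in event_times:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        S *= 1.0 - d / at_risk
        out.append(S)
    return event_times, np.asarray(out)


def km_survival_at(
    times: Sequence[float], events: Sequence[int], t: float
) -> float:
    """Kaplan-Meier survival probability at time t."""
    et, S = kaplan_meier(times, events)
    idx = np.searchsorted(et, t, side="right") - 1
    return 1.0 if idx < 0 else float(S[idx])


def log_rank(groups: Iterable[tuple[Sequence[float], Sequence[int]]]) -> tuple[float, float]:
    """K-group log-rank test; returns (chi2, p) with K-1 df.

    Standard observed-minus-expected statistic with the hypergeometric
    variance, ties handled by pooling at each distinct event time.
    """
    groups = [
        (np.asarray(t, float), np.asarray(e, int)) for t, e in groups
    ]
    K = len(groups)
    if K < 2:
        raise ValueError("need at least two groups")
    all_t = np.concatenate([t for t, _ in groups])
    all_e = np.concatenate([e for _, e in groups])
    if all_e.sum() == 0:
        raise ValueError("need at least one event overall")
    event_times = np.unique(all_t[all_e == 1])
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for t in event_times:
        n_at = np.array([np.sum(tg >= t) for tg, _ in groups], float)
        d_at = np.array(
            [np.sum((tg == t) & (eg == 1)) for tg, eg in groups], float
        )
        N = n_at.sum()
        D = d_at.sum()
        if N <= 1 or D == 0:
            continue
        O += d_at
        E += D * n_at / N
        frac = n_at / N
        mult = D * (N - D) / (N - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(stats.chi2.sf(chi2, K - 1))
    return chi2, p


def evaluate_external(
    fit: FitResult,
    cohort: Cohort,
    rule: DecisionRule | None = None,
    landmark: float = 1.0,
    n_grid: int = 40,
    n_draws: int = 200,
    seed: int = 0,
    split_by_dndsa: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score the decision rule on an external cohort.

    Per subject: risk curve from the landmark using measurements up to
    the landmark -> classification -> confusion against the observed
    outcome, reported separately for dnDSA-negative and dnDSA-positive
    subgroups.  Indeterminate predictions are counted against accuracy
    and reported in their own column.  Returns ``(metrics, per_subject)``.
    """
    rule = rule or DecisionRule()
    grid = np.linspace(landmark, rule.horizon, n_grid)
    rows = []
    for i, subj in enumerate(cohort.subjects):
        t, y = cohort.measurements_for(subj.subject_id)
        curve = risk_curve_with_ci(
            fit, subj, t, y, landmark, grid, n_draws=n_draws, seed=seed + i
        )
        label = classify_curve(curve, rule)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "dndsa": subj.dndsa,
                "observed_failure": int(subj.event == 1),
                "prediction": label,
            }
        )
    per_subject = pd.DataFrame(rows)

    def _metrics(df: pd.DataFrame, name: str) -> dict:
        n = len(df)
        base = {
            "subgroup": name,
            "n": n,
            "n_failures": int(df["observed_failure"].sum()) if n else 0,
            "n_indeterminate": int((df["prediction"] == INDETERMINATE).sum())
            if n
            else 0,
        }
        if n == 0 or df["observed_failure"].nunique() < 2:
            base.update(sensitivity=np.nan, specificity=np.nan, accuracy=np.nan)
            return base
        tp = int(
            ((df["prediction"] == PREDICTED_FAILURE) & (df["observed_failure"] == 1)).sum()
        )
        fn = int(
            ((df["prediction"] != PREDICTED_FAILURE) & (df["observed_failure"] == 1)).sum()
        )
        tn = int(
            ((df["prediction"] == PREDICTED_SURVIVAL) & (df["observed_failure"] == 0)).sum()
        )
        fp = int(
            ((df["prediction"] != PREDICTED_SURVIVAL) & (df["observed_failure"] == 0)).sum()
        )
        base.update(confusion_metrics(tp, fn, tn, fp))
        return base

    groups = [("all", per_subject)]
    if split_by_dndsa:
        groups += [
            ("dndsa_negative", per_subject[per_subject["dndsa"] == 0]),
            ("dndsa_positive", per_subject[per_subject["dndsa"] == 1]),
        ]
    metrics = pd.DataFrame([_metrics(df, name) for name, df in groups])
    return metrics, per_subject
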