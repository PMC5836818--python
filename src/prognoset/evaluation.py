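"""Classifier quality and survival separation.

AUC uses midrank handling of tied scores and therefore equals the probability
that a random recurrence sample outscores a random event-free sample, counting
ties as one half.  Kaplan-Meier curves use the product-limit estimator with the
standard events-before-censoring convention at tied times.  The log-rank test
is the unweighted two-group form; its "two-tailed" p-value is the upper tail of
the chi-square(1) distribution of the squared standardized statistic, which is
the standard two-sided interpretation for this test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .classifier import LinearClassifier, decision_scores
from .cohorts import KmRecord
from .io import ExpressionMatrix

__all__ = [
    "RocResult",
    "FiltrationVerdict",
    "KmCurve",
    "LogRankResult",
    "roc_auc",
    "auc_from_scores",
    "apply_filtration",
    "km_curve",
    "log_rank",
    "dichotomize_by_score",
]

TRAIN_AUC_THRESHOLD = 0.6
FILTER_AUC_THRESHOLD = 0.55


@dataclass
class RocResult:
    auc: float
    curve: list[tuple[float, float]]  # (false-positive rate, true-positive rate)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["fpr\ttpr"] + [f"{f:.6f}\t{t:.6f}" for f, t in self.curve]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class FiltrationVerdict:
    auc_train: float
    auc_filters: dict[str, float]
    passed: bool
    train_threshold: float = TRAIN_AUC_THRESHOLD
    filter_threshold: float = FILTER_AUC_THRESHOLD

    @property
    def failing_stage(self) -> str | None:
        if self.auc_train < self.train_threshold:
            return "train"
        for cohort, auc in self.auc_filters.items():
            if auc < self.filter_threshold:
                return f"filter:{cohort}"
        return None


@dataclass
class KmCurve:
    times: np.ndarray  # increasing event times (months)
    survival: np.ndarray  # product-limit estimate after each time
    at_risk: np.ndarray  # number at risk just before each time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p_two_tailed: float


def auc_from_scores(scores: np.ndarray, positive: np.ndarray) -> float:
    """Midrank (Mann-Whitney) AUC of ``scores`` against a boolean positive mask.

    Fast array path shared with the permutation stages; identical in value to
    :func:`roc_auc`.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(scores)  # midranks for ties
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: Mapping[str, float], labels: Mapping[str, bool]) -> RocResult:
    """ROC curve and AUC for per-sample decision scores.

    ``labels`` maps each scored sample to True (recurrence) / False.  The curve
    starts at (0,0), ends at (1,1), and its trapezoidal area equals the
    midrank AUC exactly.
    """
    samples = list(scores)
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    s = np.array([scores[k] for k in samples], dtype=float)
    y = np.array([bool(labels[k]) for k in samples])
    auc = auc_from_scores(s, y)
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    curve = list(zip(fpr.tolist(), tpr.tolist()))
    if curve[0] != (0.0, 0.0):
        curve.insert(0, (0.0, 0.0))
    return RocResult(auc=auc, curve=curve)


def apply_filtration(
    auc_train: float,
    auc_filters: Mapping[str, float],
    train_threshold: float = TRAIN_AUC_THRESHOLD,
    filter_threshold: float = FILTER_AUC_THRESHOLD,
) -> FiltrationVerdict:
    """AUC cascade verdict: pass iff training AUC >= ``train_threshold`` and
    every filtration-cohort AUC >= ``filter_threshold`` (boundary equality
    passes — the rule is "not less than")."""
    passed = auc_train >= train_threshold and all(
        a >= filter_threshold for a in auc_filters.values()
    )
    return FiltrationVerdict(
        auc_train=float(auc_train),
        auc_filters={k: float(v) for k, v in auc_filters.items()},
        passed=bool(passed),
        train_threshold=train_threshold,
        filter_threshold=filter_threshold,
    )


def km_curve(records: Sequence[KmRecord]) -> KmCurve:
    """Product-limit survival estimate for one group.

    Censored samples tied with an event time stay at risk for that event
    (events-first convention).  Times are the distinct event times only; the
    curve implicitly starts at survival 1.
    """
    if not records:
        raise ValueError("empty group")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    return KmCurve(times=event_times, survival=surv, at_risk=at_risk)


def log_rank(
    group_a: Sequence[KmRecord], group_b: Sequence[KmRecord]
) -> LogRankResult:
    """Unweighted two-group log-rank test with a chi-square(1) two-sided p."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta = np.array([r.time for r in group_a], dtype=float)
    ea = np.array([r.event for r in group_a], dtype=bool)
    tb = np.array([r.time for r in group_b], dtype=float)
    eb = np.array([r.event for r in group_b], dtype=bool)
    if not ea.any() and not eb.any():
        return LogRankResult(statistic=0.0, p_two_tailed=1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(statistic=stat, p_two_tailed=p)


def dichotomize_by_score(
    c: LinearClassifier, x: ExpressionMatrix, threshold: float = 0.0
) -> tuple[list[str], list[str]]:
    """Split samples into (high-risk, low-risk) groups by decision score.

    Samples scoring strictly above ``threshold`` are predicted high-risk.  An
    empty group triggers a warning but is still returned.
    """
    s = decision_scores(c, x)
    high = [k for k, v in s.items() if v > threshold]
    low = [k for k, v in s.items() if v <= threshold]
    if not high or not low:
        warnings.warn(
            f"score threshold {threshold} puts all {len(s)} samples on one side",
            stacklevel=2,
        )
    return high, low
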