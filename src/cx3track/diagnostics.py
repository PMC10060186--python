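"""Diagnostic performance of a dichotomized response predictor.

Evaluates a score (or a competing marker such as PD-L1 tumor proportion
score) against objective response: empirical ROC curves with DeLong AUC
confidence intervals and the Youden-optimal cutoff range, 2x2 performance
metrics with Jeffreys (Beta(1/2,1/2) posterior) intervals, Fisher's exact
association test with a conditional-MLE odds ratio, and Mann-Whitney group
comparison of raw scores.

The AUC is computed as the Mann-Whitney probability with ties counted 1/2,
which is invariant under any strictly increasing transform of the scores —
in particular it coincides with the ROC of a univariable logistic model fit
on the same scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .scoring import BiomarkerSeries, classify, max_score_by

__all__ = [
    "ClinicalRecord",
    "ConfusionMetrics",
    "RocCurve",
    "FisherResult",
    "jeffreys_interval",
    "confusion_metrics",
    "roc",
    "fisher_exact",
    "mann_whitney",
    "orr",
    "evaluate_windows",
    "table1_csv",
]

RESPONSE_CLASSES = ("CR", "PR", "SD", "PD")
PDL1_CATEGORIES = ("0%", "1-49%", ">=50%")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical outcome and covariates.

    ``responder`` follows the response-criteria convention: best response of
    complete or partial response (CR/PR) within the response window counts
    as a responder; stable or progressive disease (SD/PD) does not.
    Survival times are in months with right-censoring flags (1 = event).
    """

    patient_id: str
    best_response: str
    pd_l1_tps: str | None = None
    covariates: Mapping | None = None
    pfs_months: float | None = None
    pfs_event: bool | None = None
    os_months: float | None = None
    os_event: bool | None = None

    def __post_init__(self):
        if self.best_response not in RESPONSE_CLASSES:
            raise ValueError(f"best_response must be one of {RESPONSE_CLASSES}")
        if self.pd_l1_tps is not None and self.pd_l1_tps not in PDL1_CATEGORIES:
            raise ValueError(f"pd_l1_tps must be one of {PDL1_CATEGORIES}")
        for t in (self.pfs_months, self.os_months):
            if t is not None and t < 0:
                raise ValueError("survival times must be >= 0")

    @property
    def responder(self) -> bool:
        return self.best_response in ("CR", "PR")


def jeffreys_interval(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Jeffreys equal-tailed interval for a binomial proportion x/n.

    Central interval of the Beta(x + 1/2, n - x + 1/2) posterior, with the
    conventional boundary fix: lower bound 0 when x = 0 and upper bound 1
    when x = n.
    """
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n, n > 0")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x + 0.5, n - x + 0.5))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 0.5, n - x + 0.5))
    return lo, hi


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 performance metrics with Jeffreys 95% intervals.

    Proportions are on [0, 1]; a metric whose defining margin is empty
    (e.g. PPV with no positive calls) is ``None`` rather than 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    sensitivity_ci: tuple | None
    specificity_ci: tuple | None
    ppv_ci: tuple | None
    npv_ci: tuple | None
    accuracy_ci: tuple

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        out = {}
        for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, k)
            out[k] = None if v is None else v * scale
        return out


def _prop(x: int, n: int):
    if n == 0:
        return None, None
    return x / n, jeffreys_interval(x, n)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy from 2x2 counts."""
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty table")
    sens, sens_ci = _prop(tp, tp + fn)
    spec, spec_ci = _prop(tn, tn + fp)
    ppv, ppv_ci = _prop(tp, tp + fp)
    npv, npv_ci = _prop(tn, tn + fn)
    acc = (tp + tn) / n
    return ConfusionMetrics(
        tp, fp, fn, tn, sens, spec, ppv, npv, acc,
        sens_ci, spec_ci, ppv_ci, npv_ci, jeffreys_interval(tp + tn, n),
    )


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC with DeLong AUC inference and Youden cutoff range.

    ``thresholds`` are descending candidate cutoffs (observed scores plus
    +/-inf sentinels); a score is called positive when score >= threshold,
    so the curve runs from (0, 0) at +inf to (1, 1) at -inf in
    (1 - specificity, sensitivity) space.

    ``youden_interval`` is the half-open band (low, high] of cutoffs theta
    that all yield the same positive set and attain the maximal Youden index
    J = sensitivity + specificity - 1: ``high`` is the smallest observed
    score called positive at the optimum and ``low`` the largest observed
    score below it.  Reporting the band mirrors the fact that any cutoff
    inside it is equally optimal on the data.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple
    youden_interval: tuple
    youden_max: float


def _auc_delong(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC (midrank / Mann-Whitney) and DeLong standard error."""
    m, n = len(pos), len(neg)
    # placement values: V10_i = P_hat(pos_i > neg), ties 1/2
    allv = np.concatenate([pos, neg])
    order = stats.rankdata(allv)  # midranks
    r_pos = order[:m]
    r_neg = order[m:]
    r_pos_within = stats.rankdata(pos)
    r_neg_within = stats.rankdata(neg)
    v10 = (r_pos - r_pos_within) / n
    v01 = 1.0 - (r_neg - r_neg_within) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    return auc, se


def roc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC of ``scores`` for predicting boolean ``labels``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)

    uniq = np.unique(s)[::-1]  # descending observed scores
    thresholds = np.concatenate([[np.inf], uniq, [-np.inf]])
    sens = np.array([(pos >= t).sum() / m for t in thresholds])
    spec = np.array([(neg < t).sum() / n for t in thresholds])

    auc, se = _auc_delong(pos, neg)
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))

    j = sens + spec - 1.0
    # restrict the optimum to finite observed cutoffs (sentinels give J = 0)
    finite = np.isfinite(thresholds)
    jmax = j[finite].max()
    attain = thresholds[finite & (j >= jmax - 1e-12)]
    # band spans all observed cutoffs tying on J, extended down to (but
    # excluding) the next observed score below the least of them
    high = float(attain.max())
    below = uniq[uniq < float(attain.min())]
    low = float(below.max()) if below.size else -math.inf
    return RocCurve(thresholds, sens, spec, auc, se, ci, (low, high), float(jmax))


@dataclass(frozen=True)
class FisherResult:
    """Fisher exact test on a 2x2 table.

    ``odds_ratio`` is the conditional maximum-likelihood estimate under the
    noncentral hypergeometric model with an exact (test-inversion) interval;
    ``or_sample`` is the plain cross-product ad/bc.  Both are surfaced
    because they can differ substantially in small tables.
    """

    p_two_sided: float
    odds_ratio: float
    or_ci: tuple
    or_sample: float


def fisher_exact(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    The two-sided p sums the probabilities of all tables with the observed
    margins whose hypergeometric probability does not exceed that of the
    observed table (probability-mass ordering).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=int)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return FisherResult(1.0, float("nan"), (float("nan"), float("nan")),
                            float("nan"))
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    res = _scipy_odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    or_sample = (a * d) / (b * c) if b * c > 0 else math.inf
    return FisherResult(p, float(res.statistic), (float(ci.low), float(ci.high)),
                        or_sample)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for x) with two-sided p.

    Exact enumeration when the pooled sample is small (n <= 12) and tie
    free; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(1.0, res.pvalue))


def orr(records: Iterable[ClinicalRecord]) -> dict:
    """Overall response rate: (CR + PR) / n x 100, with Jeffreys interval."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    n = len(records)
    r = sum(rec.responder for rec in records)
    lo, hi = jeffreys_interval(r, n)
    return {"n": n, "responders": r, "orr_pct": 100.0 * r / n,
            "ci_pct": (100.0 * lo, 100.0 * hi)}


def evaluate_windows(
    series_list: Sequence[BiomarkerSeries],
    records: Sequence[ClinicalRecord],
    windows: Sequence[float] = (3, 4, 6, 9),
    theta: float = 10.0,
    relative: bool = False,
) -> dict:
    """Per-window 2x2 performance of the dichotomized score vs response.

    Only patients evaluable in a window enter its table, so the evaluable n
    varies with the measurement schedule and dropout.  Windows with fewer
    than two evaluable patients or a single response class are flagged and
    not computed.
    """
    by_id = {r.patient_id: r for r in records}
    unmatched = [s.patient_id for s in series_list if s.patient_id not in by_id]
    if unmatched:
        raise ValueError(f"no clinical record for patients: {unmatched}")
    out = {}
    for w in windows:
        tp = fp = fn = tn = 0
        n_eval = 0
        classes = set()
        for s in series_list:
            res = max_score_by(s, w, relative=relative)
            if not res.evaluable:
                continue
            n_eval += 1
            high = classify(res, theta) == "high"
            resp = by_id[s.patient_id].responder
            classes.add(resp)
            tp += high and resp
            fp += high and not resp
            fn += (not high) and resp
            tn += (not high) and not resp
        if n_eval < 2 or len(classes) < 2:
            out[w] = {"n": n_eval, "flag": "insufficient data", "metrics": None,
                      "fisher": None}
            continue
        out[w] = {
            "n": n_eval,
            "flag": None,
            "metrics": confusion_metrics(tp, fp, fn, tn),
            "fisher": fisher_exact(tp, fp, fn, tn),
        }
    return out


def table1_csv(columns: Mapping[str, ConfusionMetrics], path=None) -> pd.DataFrame:
    """Shape per-marker/window metrics as a performance table.

    Rows PPV/NPV/sensitivity/specificity/accuracy, one column per marker or
    window, each cell ``"83.3% (10/12)"``.
    """
    def cell(p, num, den):
        return "NA" if p is None else f"{100 * p:.1f}% ({num}/{den})"

    rows = {}
    for name, m in columns.items():
        rows[name] = {
            "PPV": cell(m.ppv, m.tp, m.tp + m.fp),
            "NPV": cell(m.npv, m.tn, m.tn + m.fn),
            "Sensitivity": cell(m.sensitivity, m.tp, m.tp + m.fn),
            "Specificity": cell(m.specificity, m.tn, m.tn + m.fp),
            "Accuracy": cell(m.accuracy, m.tp + m.tn, m.n),
        }
    df = pd.DataFrame(rows).loc[["PPV", "NPV", "Sensitivity", "Specificity", "Accuracy"]]
    if path is not None:
        df.to_csv(path, index_label="metric")
    return df
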