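"""Diagnostics: 2x2 metrics, Jeffreys intervals, ROC/AUC/Youden, exact tests.

Expected values come from independent oracles computed in this file:
exhaustive pair counting for the AUC, full hypergeometric enumeration for
Fisher's test, numerical Beta-density integration for Jeffreys quantiles,
and assignment enumeration for the small-sample Mann-Whitney p.
"""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from cx3track.diagnostics import (
    ClinicalRecord,
    confusion_metrics,
    evaluate_windows,
    fisher_exact,
    jeffreys_interval,
    mann_whitney,
    orr,
    roc,
)
from cx3track.scoring import BiomarkerSeries


# ---------------------------------------------------------------- 2x2 metrics

def test_perfect_and_degenerate_margins():
    m = confusion_metrics(5, 0, 0, 0)
    assert m.sensitivity == 1.0 and m.accuracy == 1.0
    assert m.specificity is None and m.npv is None  # empty margins undefined


def test_jeffreys_against_numeric_beta_quantile_oracle():
    """Central 95% interval of Beta(x+1/2, n-x+1/2) for 15/17, by
    integrating the Beta density and root-finding the quantiles."""
    a, b = 15.5, 2.5
    norm = integrate.quad(lambda t: t ** (a - 1) * (1 - t) ** (b - 1), 0, 1)[0]

    def cdf(q):
        return integrate.quad(
            lambda t: t ** (a - 1) * (1 - t) ** (b - 1), 0, q)[0] / norm

    lo_oracle = optimize.brentq(lambda q: cdf(q) - 0.025, 1e-9, 1 - 1e-9)
    hi_oracle = optimize.brentq(lambda q: cdf(q) - 0.975, 1e-9, 1 - 1e-9)
    lo, hi = jeffreys_interval(15, 17)
    assert lo == pytest.approx(lo_oracle, abs=1e-8)
    assert hi == pytest.approx(hi_oracle, abs=1e-8)


def test_jeffreys_boundaries():
    assert jeffreys_interval(0, 10)[0] == 0.0
    assert jeffreys_interval(10, 10)[1] == 1.0


def test_jeffreys_interval_contains_point_estimate():
    for x, n in [(1, 17), (8, 17), (16, 17), (3, 5)]:
        lo, hi = jeffreys_interval(x, n)
        assert lo <= x / n <= hi


def test_jeffreys_empirical_coverage():
    """>= 93% coverage at n=17 across p = 0.1..0.9, 10,000 replicates."""
    rng = np.random.default_rng(2024)
    n = 17
    bounds = np.array([jeffreys_interval(x, n) for x in range(n + 1)])
    for p in np.arange(0.1, 0.95, 0.1):
        xs = rng.binomial(n, p, size=10_000)
        cover = (bounds[xs, 0] <= p) & (p <= bounds[xs, 1])
        assert cover.mean() >= 0.93, f"coverage {cover.mean():.3f} at p={p:.1f}"


# ----------------------------------------------------------------------- ROC

def _auc_pair_count(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([3, 2, 1, 0], [1, 1, 0, 0], 1.0),
        ([3, 1, 2, 0], [1, 1, 0, 0], 0.75),
        ([1, 1, 1, 1], [1, 0, 1, 0], 0.5),
    ],
)
def test_auc_matches_pair_counting(scores, labels, expected):
    labels = [bool(y) for y in labels]
    curve = roc(scores, labels)
    assert curve.auc == pytest.approx(expected)
    assert curve.auc == pytest.approx(_auc_pair_count(scores, labels))


@settings(derandomize=True, max_examples=80)
@given(st.lists(st.tuples(st.floats(-50, 50, allow_nan=False), st.booleans()),
                min_size=4, max_size=30))
def test_auc_equals_pair_count_oracle_and_curve_endpoints(data):
    scores = [s for s, _ in data]
    labels = [y for _, y in data]
    if all(labels) or not any(labels):
        return
    curve = roc(scores, labels)
    assert curve.auc == pytest.approx(_auc_pair_count(scores, labels), abs=1e-12)
    assert curve.sens[0] == 0.0 and curve.spec[0] == 1.0
    assert curve.sens[-1] == 1.0 and curve.spec[-1] == 0.0
    assert np.all(np.diff(curve.sens) >= -1e-12)


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.tuples(st.floats(-20, 20, allow_nan=False), st.booleans()),
                min_size=4, max_size=20))
def test_auc_invariant_under_strictly_increasing_transform(data):
    # quantize so the transform below is strictly increasing in floats
    scores = np.round(np.array([s for s, _ in data]), 3)
    labels = [y for _, y in data]
    if all(labels) or not any(labels):
        return
    transformed = np.exp(scores / 10.0) + 3 * scores
    assert roc(scores, labels).auc == pytest.approx(
        roc(transformed, labels).auc, abs=1e-12)


def test_youden_interval_endpoints_attain_max_j():
    rng = np.random.default_rng(7)
    scores = np.round(rng.normal(0, 5, 40), 1)
    labels = rng.random(40) < stats.norm.cdf(scores / 5)
    if labels.all() or not labels.any():
        pytest.skip("degenerate draw")
    curve = roc(scores, labels)
    pos, neg = scores[labels], scores[~labels]

    def j_at(t):
        return (pos >= t).mean() + (neg < t).mean() - 1.0

    low, high = curve.youden_interval
    assert j_at(high) == pytest.approx(curve.youden_max)
    # any threshold strictly inside the band yields the same J
    inside = (low + high) / 2 if np.isfinite(low) else high - 0.05
    assert j_at(inside) == pytest.approx(curve.youden_max)


def test_youden_band_on_separated_scores():
    """Perfect separation: the band spans the gap between the groups."""
    scores = [9.42, 5.0, 2.0, 10.35, 15.0, 20.0]
    labels = [False, False, False, True, True, True]
    curve = roc(scores, labels)
    assert curve.auc == 1.0
    assert curve.youden_interval == (9.42, 10.35)
    assert curve.youden_max == pytest.approx(1.0)


def test_delong_variance_is_calibrated():
    """Mean DeLong variance tracks the Monte-Carlo variance of the AUC."""
    rng = np.random.default_rng(99)
    aucs, variances = [], []
    for _ in range(400):
        pos = rng.normal(1.0, 1.0, 25)
        neg = rng.normal(0.0, 1.0, 25)
        curve = roc(np.concatenate([pos, neg]),
                    [True] * 25 + [False] * 25)
        aucs.append(curve.auc)
        variances.append(curve.auc_se**2)
    ratio = np.mean(variances) / np.var(aucs, ddof=1)
    assert 0.7 < ratio < 1.4


def test_roc_rejects_single_class():
    with pytest.raises(ValueError):
        roc([1.0, 2.0], [True, True])


# -------------------------------------------------------------- Fisher exact

def _fisher_enumeration(a, b, c, d):
    """Two-sided p by full enumeration of the hypergeometric support."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def _cmle_or_oracle(a, b, c, d):
    """Conditional MLE of the odds ratio by maximizing the noncentral
    hypergeometric likelihood on a log grid + golden section."""
    r1, r2, c1 = a + b, c + d, a + c
    support = range(max(0, c1 - r2), min(r1, c1) + 1)

    def neg_loglik(log_psi):
        psi = math.exp(log_psi)
        weights = [comb(r1, x) * comb(r2, c1 - x) * psi**x for x in support]
        return -(a * log_psi - math.log(sum(weights)))

    res = optimize.minimize_scalar(neg_loglik, bounds=(-10, 10),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return math.exp(res.x)


@pytest.mark.parametrize("table", [(10, 2, 2, 15), (7, 5, 1, 15), (3, 9, 8, 4),
                                   (10, 2, 2, 17)])
def test_fisher_p_equals_enumeration_oracle(table):
    res = fisher_exact(*table)
    assert res.p_two_sided == pytest.approx(_fisher_enumeration(*table),
                                            abs=1e-12)


@pytest.mark.parametrize("table", [(10, 2, 2, 15), (7, 5, 1, 15)])
def test_conditional_mle_or_matches_grid_oracle(table):
    res = fisher_exact(*table)
    assert res.odds_ratio == pytest.approx(_cmle_or_oracle(*table), rel=1e-5)
    assert res.or_ci[0] < res.odds_ratio < res.or_ci[1]


def test_fisher_symmetric_table():
    res = fisher_exact(5, 5, 5, 5)
    assert res.p_two_sided == pytest.approx(1.0)
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
    assert res.or_sample == 1.0


def test_fisher_zero_margin():
    res = fisher_exact(0, 0, 3, 5)
    assert res.p_two_sided == 1.0
    assert math.isnan(res.odds_ratio)


# -------------------------------------------------------------- Mann-Whitney

def test_mann_whitney_extremes():
    u, p = mann_whitney([10, 11, 12], [1, 2])
    assert u == 6  # n_x * n_y, all x greater
    x = [1.0, 2.0, 3.0, 4.0]
    _, p_same = mann_whitney(x, x)
    assert p_same == pytest.approx(1.0, abs=0.05)


def test_mann_whitney_exact_enumeration_oracle():
    """x={1,2,3}, y={4,5}: p from enumerating all C(5,2) assignments."""
    pooled = [1, 2, 3, 4, 5]
    u_obs = sum(1 for a in [1, 2, 3] for b in [4, 5] if a > b)  # = 0

    def u_of(xs):
        ys = [v for v in pooled if v not in xs]
        return sum(1 for a in xs for b in ys if a > b)

    us = [u_of(xs) for xs in itertools.combinations(pooled, 3)]
    mu = 3 * 2 / 2
    p_oracle = sum(1 for u in us if abs(u - mu) >= abs(u_obs - mu)) / len(us)
    u, p = mann_whitney([1, 2, 3], [4, 5])
    assert u == u_obs
    assert p == pytest.approx(p_oracle, abs=1e-12)


# --------------------------------------------------------- ORR and windowing

def _records(pairs):
    return [ClinicalRecord(f"P{i}", br) for i, br in enumerate(pairs)]


def test_orr_values():
    res = orr(_records(["PR"] * 12 + ["SD"] * 13 + ["PD"] * 4))
    assert res["orr_pct"] == pytest.approx(100 * 12 / 29)
    assert orr(_records(["SD"] * 5))["orr_pct"] == 0.0
    assert orr(_records(["CR"] * 5))["orr_pct"] == 100.0


def _cohort(scores_by_id, responders, weeks=(3, 6)):
    series, records = [], []
    for pid, sc in scores_by_id.items():
        meas = [(0.0, 30.0)] + [(w, min(100.0, 30.0 + sc)) for w in weeks]
        series.append(BiomarkerSeries(pid, tuple(meas)))
        records.append(ClinicalRecord(pid, "PR" if pid in responders else "SD"))
    return series, records


def test_evaluate_windows_counts_and_flags():
    series, records = _cohort(
        {"A": 15.0, "B": 12.0, "C": 2.0, "D": -3.0}, responders={"A", "B"})
    out = evaluate_windows(series, records, windows=(6,), theta=10)
    m = out[6]["metrics"]
    assert (m.tp, m.fp, m.fn, m.tn) == (2, 0, 0, 2)
    assert m.accuracy == 1.0

    # window with no on-treatment measurements is flagged, not computed
    out2 = evaluate_windows(series, records, windows=(1,), theta=10)
    assert out2[1]["flag"] == "insufficient data"
    assert out2[1]["n"] == 0


def test_evaluate_windows_requires_matched_ids():
    series, records = _cohort({"A": 15.0, "B": 2.0}, responders={"A"})
    with pytest.raises(ValueError):
        evaluate_windows(series, records[:1])
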