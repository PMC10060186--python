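"""Time-to-event analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

The Cox model is maximized directly on the partial likelihood by
Newton-Raphson with step-halving, with the Efron approximation for tied
event times (Breslow available).  Wald confidence intervals and p-values
are the primary inference, matching the usual HR (95% CI, p) presentation;
a likelihood-ratio p for the whole model is also reported.  The score test
at beta = 0 is exposed because, for a single binary covariate without ties,
it is identical to the log-rank chi-square — a useful cross-check.

Times are positive (months by convention); events are right-censored only,
coded 1 = observed event.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["KMCurve", "CoxFit", "km_fit", "logrank", "cox_fit", "univariate_screen"]


def _check_times(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be 1-d of equal length")
    if len(time) == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and positive")
    return time, event


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""

    event_times: np.ndarray          # distinct observed event times, ascending
    survival: np.ndarray             # S(t) at each event time
    se: np.ndarray                   # Greenwood SE of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float                    # nan when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(time, event) -> KMCurve:
    """Kaplan-Meier estimate from right-censored data.

    The median is the earliest event time at which survival drops to 0.5 or
    below; with every subject censored the curve is constant at 1 and the
    median undefined (nan).
    """
    time, event = _check_times(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    ev_times = np.unique(time[event])
    surv, se_arr, risk, dths = [], [], [], []
    s = 1.0
    gw = 0.0  # Greenwood cumulative sum
    for t in ev_times:
        n_risk = int((time >= t).sum())
        d = int(((time == t) & event).sum())
        s *= 1.0 - d / n_risk
        if n_risk > d:
            gw += d / (n_risk * (n_risk - d))
            se_t = s * math.sqrt(gw)
        else:
            se_t = 0.0  # S has hit exactly 0
        surv.append(s)
        se_arr.append(se_t)
        risk.append(n_risk)
        dths.append(d)
    surv = np.array(surv)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(ev_times[below[0]]) if below.size else float("nan")
    return KMCurve(ev_times, surv, np.array(se_arr), np.array(risk),
                   np.array(dths), median)


def logrank(time, event, group) -> tuple[float, int, float]:
    """Log-rank (Mantel-Cox) test across two or more groups.

    Sums observed-minus-expected event counts over event times with the
    hypergeometric covariance; returns (chi-square, df, p) with
    df = number of groups - 1.
    """
    time, event = _check_times(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank requires at least two groups")
    if not event.any():
        raise ValueError("log-rank requires at least one event")
    gidx = np.searchsorted(labels, group)
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        d = (event & (time == t)).sum()
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[event & (time == t)], minlength=k).astype(float)
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            f = d * (n - d) / (n - 1)
            cov += f * (np.diag(n_g / n) - np.outer(n_g, n_g) / n**2)
    v = o_minus_e[:-1]
    vcov = cov[:-1, :-1]
    chi2 = float(v @ np.linalg.pinv(vcov) @ v)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass(frozen=True)
class CoxFit:
    """Fitted Cox proportional-hazards model."""

    names: tuple
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool
    score_chi2: float                 # score test at beta = 0
    ties: str = "efron"
    warnings_: tuple = field(default_factory=tuple)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def hr_ci(self) -> np.ndarray:
        z = 1.959963984540054
        return np.exp(np.stack([self.coef - z * self.se, self.coef + z * self.se],
                               axis=1))

    @property
    def p_wald(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def p_lr(self) -> float:
        """Likelihood-ratio p for the whole model."""
        lr = 2.0 * (self.loglik - self.loglik_null)
        return float(stats.chi2.sf(max(lr, 0.0), len(self.coef)))

    def summary(self):
        import pandas as pd

        ci = self.hr_ci
        return pd.DataFrame({
            "coef": self.coef, "HR": self.hr,
            "HR_lo95": ci[:, 0], "HR_hi95": ci[:, 1],
            "se": self.se, "p": self.p_wald,
        }, index=list(self.names))


def _partial_loglik(beta, time, event, X, ties):
    """Log partial likelihood, gradient and information (negative Hessian).

    Risk sets are handled by iterating distinct event times; within a tied
    group of d events the Efron correction subtracts l/d of the tied
    group's own contribution from the risk-set sums, l = 0..d-1.  Breslow
    uses the full risk-set sums for every tied event.
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow in exp for diverging coefficients
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(time[event]):
        risk = time >= t
        dead = event & (time == t)
        d = int(dead.sum())
        s0 = w[risk].sum()
        s1 = w[risk] @ X[risk]
        s2 = (w[risk, None] * X[risk]).T @ X[risk]
        s0d = w[dead].sum()
        s1d = w[dead] @ X[dead]
        s2d = (w[dead, None] * X[dead]).T @ X[dead]
        ll += eta[dead].sum()
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            a0 = s0 - frac * s0d
            a1 = s1 - frac * s1d
            a2 = s2 - frac * s2d
            ll -= math.log(a0)
            grad_term = a1 / a0
            info += a2 / a0 - np.outer(grad_term, grad_term)
            grad -= grad_term
    grad += X[event].sum(axis=0)
    return ll, grad, info


def cox_fit(time, event, X, names=None, ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 100) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the partial likelihood.

    Parameters
    ----------
    time, event
        Right-censored follow-up (months) and event indicators.
    X
        (n, p) covariate matrix or 1-d array for a single covariate.
    ties
        ``"efron"`` (default) or ``"breslow"``; identical on tie-free data.

    Raises on zero-variance or collinear covariates (detected from the
    conditioning of the information matrix at beta = 0).  Monotone partial
    likelihood (perfect separation) is reported as ``converged=False`` with
    a warning rather than an error.
    """
    time, event = _check_times(time, event)
    if not event.any():
        raise ValueError("Cox fit requires at least one event")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(time):
        raise ValueError("X rows must match number of subjects")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    names = tuple(names) if names is not None else tuple(f"x{i}" for i in range(p))
    if len(names) != p:
        raise ValueError("names length must match covariates")

    sd = X.std(axis=0)
    zero_var = [names[i] for i in range(p) if sd[i] == 0]
    if zero_var:
        raise ValueError(f"zero-variance covariates: {zero_var}")

    beta = np.zeros(p)
    ll, grad, info = _partial_loglik(beta, time, event, X, ties)
    # collinearity check on the baseline information matrix
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e10:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"collinear covariates (information matrix singular): "
                         f"{pairs or names}")
    score_chi2 = float(grad @ np.linalg.solve(info, grad))
    ll_null = ll

    warns = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(info, grad)
        # step-halving keeps the partial log-likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new, grad_new, info_new = _partial_loglik(beta_new, time, event, X, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        if rel < tol:
            converged = True
            break

    if np.any(np.abs(beta) > 15):
        converged = False
        msg = ("diverging coefficient(s) — likely monotone partial likelihood "
               "(perfect separation)")
        warns.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(names, beta, se, float(ll), float(ll_null), it, converged,
                  score_chi2, ties, tuple(warns))


def univariate_screen(time, event, covariates, alpha_keep: float = 0.10,
                      ties: str = "efron") -> dict:
    """Univariate Cox screen followed by a joint multivariable fit.

    Each covariate is fit alone; those with Wald p below ``alpha_keep``
    enter the joint model.  The screening threshold is a parameter (0.10 by
    default, the permissive convention for hypothesis-generating screens).
    Returns ``{"univariate": {name: CoxFit}, "retained": [...],
    "multivariable": CoxFit | None}``.
    """
    import pandas as pd

    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    uni = {}
    retained = []
    for j, name in enumerate(names):
        fit = cox_fit(time, event, X[:, j], names=[name], ties=ties)
        uni[name] = fit
        if fit.p_wald[0] < alpha_keep:
            retained.append(name)
    multi = None
    if retained:
        idx = [names.index(nm) for nm in retained]
        multi = cox_fit(time, event, X[:, idx], names=retained, ties=ties)
    return {"univariate": uni, "retained": retained, "multivariable": multi}
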