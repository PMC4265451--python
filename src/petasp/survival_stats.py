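"""Outcome-analysis machinery: correlations, Cox regression, optimal
cutoffs, multivariate selection, Kaplan-Meier and log-rank.

The screening procedure implemented by :func:`optimal_cutoff` binarizes
a metric covariate at every distinct observed value inside its
interquartile range, fits a univariate proportional-hazards model to
each indicator ``[x > v]``, and reports the cutoff with the largest
Wald |z| (smallest p).  Restricting candidates to the IQR avoids tiny
groups; no multiplicity correction is applied across the scan, so the
selected p-value is anti-conservative — the full scan table is returned
so the inflation is visible.

Cox partial likelihoods use Efron's tie approximation throughout and
are maximized by a damped Newton iteration written against the explicit
gradient/Hessian; Kaplan-Meier and the log-rank test are delegated to
lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

_BETA_CAP = 15.0


# ---------------------------------------------------------------------------
# Correlation


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation on midranks with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


@dataclass(frozen=True)
class CoxFit:
    """A fitted proportional-hazards model.

    Arrays are indexed by covariate.  ``hr`` is exp(beta); the 95% CI is
    the Wald interval exp(beta +- 1.96 se).  ``monotone`` flags covariates
    whose likelihood is monotone (perfect separation); their beta is
    capped and the Wald statistics are unreliable.
    """

    covariates: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    monotone: bool = False

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        d = 1.959963984540054 * self.se
        return np.exp(self.beta - d), np.exp(self.beta + d)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame(
            {
                "variable": self.covariates,
                "hr": self.hr,
                "ci95_low": lo,
                "ci95_high": hi,
                "z": self.z,
                "p": self.p,
                "n": self.n,
                "events": self.n_events,
            }
        )


def _efron_ll_grad_hess(beta, X, order, event_blocks):
    """Log partial likelihood, gradient and Hessian (Efron ties).

    ``order`` sorts subjects by descending time; ``event_blocks`` lists,
    per unique event time (descending), the slice of tied deaths in the
    sorted arrays together with the size of the risk set prefix.
    """
    p = X.shape[1]
    Xs = X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * Xs, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for risk_end, d_lo, d_hi in event_blocks:
        m = d_hi - d_lo
        S_R = cw[risk_end - 1]
        Z_R = cwx[risk_end - 1]
        Q_R = cwxx[risk_end - 1]
        wd = w[d_lo:d_hi]
        Xd = Xs[d_lo:d_hi]
        S_D = wd.sum()
        Z_D = (wd[:, None] * Xd).sum(axis=0)
        Q_D = (wd[:, None, None] * (Xd[:, :, None] * Xd[:, None, :])).sum(axis=0)

        ll += eta[d_lo:d_hi].sum()
        grad += Xd.sum(axis=0)
        frac = np.arange(m) / m
        denom = S_R - frac * S_D  # (m,)
        ll -= np.log(denom).sum()
        mu = (Z_R[None, :] - frac[:, None] * Z_D[None, :]) / denom[:, None]  # (m, p)
        grad -= mu.sum(axis=0)
        q = (Q_R[None] - frac[:, None, None] * Q_D[None]) / denom[:, None, None]
        hess -= (q - mu[:, :, None] * mu[:, None, :]).sum(axis=0)
    return ll, grad, hess


def _prepare_blocks(time: np.ndarray, event: np.ndarray):
    """Sort by descending time (deaths first within ties) and list the
    death blocks: (risk-set prefix length, death slice lo, hi)."""
    n = len(time)
    order = np.lexsort((1 - event, -time))
    ts = time[order]
    es = event[order]
    blocks = []
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d_hi = i
        while d_hi < j and es[d_hi]:
            d_hi += 1
        if d_hi > i:
            blocks.append((j, i, d_hi))
        i = j
    return order, blocks


def _fit_core(
    Xc: np.ndarray,
    order: np.ndarray,
    blocks: list,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton maximization of the Efron partial likelihood.

    ``Xc`` should be column-centered for conditioning (beta unaffected).
    Returns (beta, se, monotone_flag).
    """
    p = Xc.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _efron_ll_grad_hess(beta, Xc, order, blocks)
    monotone = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            monotone = True
            break
        t = 1.0
        for _half in range(30):
            beta_new = beta + t * step
            ll_new, grad_new, hess_new = _efron_ll_grad_hess(beta_new, Xc, order, blocks)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        if np.abs(beta).max() > _BETA_CAP:
            monotone = True
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            ll, grad, hess = _efron_ll_grad_hess(beta, Xc, order, blocks)
            break
        if np.abs(grad).max() < tol * max(1.0, abs(ll)):
            break
    if monotone:
        warnings.warn(
            "monotone partial likelihood (perfect separation); beta capped",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    return beta, se, monotone


def cox_fit(
    data: pd.DataFrame,
    covariates: str | list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxFit:
    """Fit a proportional-hazards model by Newton iteration.

    Efron handling of tied event times; Wald z and p per covariate;
    95% CI = exp(beta +- 1.96 se).  A monotone likelihood (perfect
    separation) is flagged and beta capped rather than diverging.
    """
    if isinstance(covariates, str):
        covariates = [covariates]
    X = np.asarray(data[covariates], dtype=float)
    time = np.asarray(data[duration_col], dtype=float)
    event = np.asarray(data[event_col], dtype=int)
    n, p = X.shape
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("need at least 2 events")
    for j, name in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant covariate {name!r}")

    order, blocks = _prepare_blocks(time, event)
    beta, se, monotone = _fit_core(X - X.mean(axis=0), order, blocks, max_iter, tol)
    return CoxFit(
        covariates=tuple(covariates),
        beta=beta,
        se=se,
        n=n,
        n_events=n_events,
        monotone=monotone,
    )


# ---------------------------------------------------------------------------
# Optimal cutoff scan


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the IQR-constrained maximally selected cutoff scan.

    ``direction`` is ">" when the high-covariate group carries the
    excess hazard (reported HR >= 1 after normalisation; "<" means the
    indicator was inverted to ``[x <= cutoff]``).  ``scan`` holds one
    row per candidate with its Wald statistics before normalisation.
    """

    cutoff: float
    direction: str
    fit: CoxFit
    scan: pd.DataFrame
    covariate: str


def _quartiles(x: np.ndarray, method: str = "linear") -> tuple[float, float]:
    return tuple(np.quantile(x, [0.25, 0.75], method=method))


def optimal_cutoff(
    data: pd.DataFrame,
    covariate: str,
    duration_col: str = "time_months",
    event_col: str = "event",
    quartile_method: str = "linear",
) -> CutoffResult:
    """Scan distinct covariate values within the IQR for the cutoff with
    the most significant binarized hazard ratio.

    Candidates are the distinct observed values v with Q1 <= v <= Q3
    (quartiles by linear interpolation of order statistics by default).
    For each candidate a univariate model on the indicator ``x > v`` is
    fitted; the candidate with maximum |Wald z| wins, ties broken toward
    the smaller cutoff.  The reported fit is normalised so HR >= 1 (the
    group labels are inverted when the high group is protective).
    """
    x = np.asarray(data[covariate], dtype=float)
    q1, q3 = _quartiles(x, quartile_method)
    candidates = np.unique(x[(x >= q1) & (x <= q3)])
    candidates = [v for v in candidates if 0 < (x > v).sum() < len(x)]
    if len(candidates) < 3:
        raise ValueError("need at least 3 usable distinct covariate values within the IQR")

    time = np.asarray(data[duration_col], dtype=float)
    event = np.asarray(data[event_col], dtype=int)
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("need at least 2 events")
    # the risk-set structure depends only on (time, event): share it
    # across all candidate indicators
    order, blocks = _prepare_blocks(time, event)

    rows = []
    fits = {}
    for v in candidates:
        ind = (x > v).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                beta, se, monotone = _fit_core(
                    (ind - ind.mean())[:, None], order, blocks
                )
        except (ValueError, np.linalg.LinAlgError):
            continue
        fit = CoxFit(
            covariates=(f"{covariate}>cutoff",),
            beta=beta,
            se=se,
            n=len(x),
            n_events=n_events,
            monotone=monotone,
        )
        fits[v] = fit
        rows.append(
            {
                "candidate": v,
                "n_high": int(ind.sum()),
                "hr": float(fit.hr[0]),
                "z": float(fit.z[0]),
                "p": float(fit.p[0]),
            }
        )
    if not rows:
        raise ValueError("no candidate cutoff yields a fittable model")
    scan = pd.DataFrame(rows)
    best_idx = scan["z"].abs().round(12).idxmax()
    # ties toward smaller cutoff: idxmax returns first occurrence and
    # scan rows are in increasing candidate order
    best = scan.loc[best_idx]
    v = float(best["candidate"])
    fit = fits[v]
    if fit.beta[0] >= 0:
        direction = ">"
        norm_fit = fit
    else:
        # invert group labels: indicator [x <= v]; beta flips sign exactly
        direction = "<"
        norm_fit = CoxFit(
            covariates=(f"{covariate}<=cutoff",),
            beta=-fit.beta,
            se=fit.se,
            n=fit.n,
            n_events=fit.n_events,
            monotone=fit.monotone,
        )
    return CutoffResult(cutoff=v, direction=direction, fit=norm_fit, scan=scan, covariate=covariate)


# ---------------------------------------------------------------------------
# Multivariate selection


@dataclass(frozen=True)
class SelectionResult:
    univariate: pd.DataFrame
    admitted: tuple[str, ...]
    collinear_dropped: tuple[str, ...]
    eliminated: tuple[str, ...]
    final: CoxFit | None


def multivariate_select(
    data: pd.DataFrame,
    candidates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    admit_p: float = 0.10,
    collinearity_rho: float = 0.9,
    retain_p: float = 0.05,
) -> SelectionResult:
    """Univariate screening, collinearity pruning and backward elimination.

    Covariates with univariate Wald p <= ``admit_p`` enter; among
    admitted pairs with |Spearman rho| >= ``collinearity_rho`` the one
    with the larger univariate p is dropped (this is what removes TLG in
    favour of MTV when the two are near-collinear).  The joint model is
    then reduced by backward elimination, removing the largest Wald p
    above ``retain_p`` one covariate at a time.
    """
    uni_rows = []
    uni_p = {}
    for name in candidates:
        fit = cox_fit(data, name, duration_col, event_col)
        uni_p[name] = float(fit.p[0])
        lo, hi = fit.ci95
        uni_rows.append(
            {
                "variable": name,
                "hr": float(fit.hr[0]),
                "ci95_low": float(lo[0]),
                "ci95_high": float(hi[0]),
                "p": float(fit.p[0]),
            }
        )
    univariate = pd.DataFrame(uni_rows)

    admitted = [name for name in candidates if uni_p[name] <= admit_p]
    if not admitted:
        raise ValueError("no covariate admitted at the univariate screening threshold")

    collinear_dropped: list[str] = []
    kept = list(admitted)
    changed = True
    while changed:
        changed = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                rho, _ = spearman(data[a].to_numpy(), data[b].to_numpy())
                if abs(rho) >= collinearity_rho:
                    drop = a if uni_p[a] > uni_p[b] else b
                    kept.remove(drop)
                    collinear_dropped.append(drop)
                    changed = True
                    break
            if changed:
                break

    eliminated: list[str] = []
    current = list(kept)
    final = cox_fit(data, current, duration_col, event_col)
    while len(current) > 1:
        pvals = final.p
        worst = int(np.argmax(pvals))
        if pvals[worst] <= retain_p:
            break
        eliminated.append(current.pop(worst))
        final = cox_fit(data, current, duration_col, event_col)
    return SelectionResult(
        univariate=univariate,
        admitted=tuple(admitted),
        collinear_dropped=tuple(collinear_dropped),
        eliminated=tuple(eliminated),
        final=final,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve with at-risk counts and censor marks."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


def km_estimate(durations: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate of one group."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array(
        [int((durations >= t).sum()) for t in timeline], dtype=int
    )
    return KMCurve(
        times=timeline,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(durations[events == 0]),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """S(t) of a KM curve (right-continuous step function)."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def logrank(
    durations: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p), 1 df."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("log-rank requires exactly two groups")
    a = groups == labels[0]
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    res = logrank_test(durations[a], durations[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)
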