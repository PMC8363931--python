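"""Survival-association statistics: Cox screens with Bonferroni correction,
proportional-hazards diagnostics, and the auxiliary nonparametric tests.

The Cox partial likelihood (Efron handling of tied event times) is maximized
by Newton iterations on internally standardized covariates, with step
halving, to a gradient infinity-norm below 1e-8.  Confidence intervals and
p-values are Wald-based: CI = exp(beta +- 1.96 * SE).  The proportional-
hazards diagnostic regresses scaled Schoenfeld residuals on event times
(Grambsch-Therneau score test, identity time transform).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "CoxResult", "CoxFit", "ConvergenceError",
    "cox_fit", "bonferroni", "ph_test", "logrank",
    "mann_whitney", "spearman", "run_screen",
    "DEFAULT_ADJUSTERS",
]

DEFAULT_ADJUSTERS = ("age", "sex", "side", "stage", "histology")

Z_95 = 1.96  # Wald 95% multiplier


class ConvergenceError(RuntimeError):
    """Newton failed: no convergence within the iteration budget, or a
    monotone likelihood (perfect separation)."""


@dataclass
class CoxResult:
    """One covariate's row of a Cox model."""

    variable: str
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    p_corrected: float | None = None
    ph_p: float | None = None
    model_id: str = ""


@dataclass
class CoxFit:
    """Converged Cox model with the internals needed for diagnostics."""

    variables: list[str]
    beta: np.ndarray
    cov: np.ndarray  # inverse observed information
    loglik: float
    n_used: int
    n_events: int
    # sorted (ascending time) arrays retained for residual computations
    times: np.ndarray = field(repr=False, default=None)
    events: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def results(self, model_id: str = "") -> list[CoxResult]:
        out = []
        for j, name in enumerate(self.variables):
            b, s = float(self.beta[j]), float(self.se[j])
            z = b / s
            out.append(CoxResult(
                variable=name, beta=b, se=s, hr=float(np.exp(b)),
                ci_low=float(np.exp(b - Z_95 * s)),
                ci_high=float(np.exp(b + Z_95 * s)),
                p=float(2.0 * stats.norm.sf(abs(z))),
                n_used=self.n_used, model_id=model_id))
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results()])


# ---------------------------------------------------------------------------
# partial likelihood machinery


def _efron_loglik_grad_hess(beta, times, events, X, has_ties=True):
    """Efron log partial likelihood with gradient and Hessian.

    Arrays are sorted by ascending time.  Risk sums are accumulated from the
    largest time downward; without ties the computation is fully vectorized
    (Efron reduces to Breslow), otherwise a loop visits each tied block.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; the partial likelihood is
    theta = np.exp(eta)  # invariant to a common shift of eta

    # cumulative risk sums from the end (largest time) backwards
    order = slice(None, None, -1)
    cs0 = np.cumsum(theta[order])[::-1]                       # S0 at index i
    cs1 = np.cumsum((theta[:, None] * X)[order], axis=0)[::-1]
    outer = theta[:, None, None] * (X[:, :, None] * X[:, None, :])
    cs2 = np.cumsum(outer[order], axis=0)[::-1]

    if not has_ties:
        didx = np.flatnonzero(events == 1)
        S0 = cs0[didx]
        xbar = cs1[didx] / S0[:, None]
        loglik = float(eta[didx].sum() - np.log(S0).sum())
        grad = X[didx].sum(axis=0) - xbar.sum(axis=0)
        hess = (-(cs2[didx] / S0[:, None, None]).sum(axis=0)
                + np.einsum("kp,kq->pq", xbar, xbar))
        return loglik, grad, hess

    loglik = float(eta[events == 1].sum())
    grad = X[events == 1].sum(axis=0).astype(float)
    hess = np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        d_idx = [k for k in range(i, j) if events[k] == 1]
        d = len(d_idx)
        if d:
            S0, S1, S2 = cs0[i], cs1[i], cs2[i]
            t0 = theta[d_idx].sum()
            t1 = (theta[d_idx, None] * X[d_idx]).sum(axis=0)
            t2 = outer[d_idx].sum(axis=0)
            for ell in range(d):
                f = ell / d
                phi0 = S0 - f * t0
                phi1 = S1 - f * t1
                phi2 = S2 - f * t2
                loglik -= np.log(phi0)
                xbar = phi1 / phi0
                grad -= xbar
                hess -= phi2 / phi0 - np.outer(xbar, xbar)
        i = j
    return loglik, grad, hess


def _newton(times, events, X, variables, max_iter=100, tol=1e-8,
            sep_bound=50.0):
    n, p = X.shape
    has_ties = bool(np.any(times[1:] == times[:-1]))
    beta = np.zeros(p)
    ll, grad, hess = _efron_loglik_grad_hess(beta, times, events, X, has_ties)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}")
        # step halving keeps the likelihood increasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, h_new = _efron_loglik_grad_hess(
                cand, times, events, X, has_ties)
            if ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, g_new, h_new
                break
            factor *= 0.5
        else:
            raise ConvergenceError("step halving failed to improve loglik")
        if np.max(np.abs(beta)) > sep_bound:
            raise ConvergenceError(
                "monotone likelihood (perfect separation?) for "
                f"{variables}")
    else:
        raise ConvergenceError("no convergence in 100 Newton iterations")
    cov = np.linalg.inv(-hess)
    return beta, cov, ll


def cox_fit(design: pd.DataFrame, months, events,
            ties_method: str = "efron") -> CoxFit:
    """Fit a Cox proportional-hazards model.

    ``design`` holds one column per covariate (numeric).  Rows with any
    missing value are dropped (complete-case analysis).  Requires at least
    two events and no constant covariate.  Covariates are standardized
    internally; reported coefficients are on the original scale, so the
    linear-predictor invariances (shift invariance, 1/c scaling) hold
    exactly.
    """
    if ties_method != "efron":
        raise ValueError("only Efron tie handling is implemented")
    df = design.copy()
    df["_months"] = np.asarray(months, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    df = df.dropna()
    t = df["_months"].to_numpy()
    e = df["_event"].to_numpy()
    X = df.drop(columns=["_months", "_event"]).to_numpy(dtype=float)
    variables = [c for c in design.columns]

    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant covariate(s): {bad}")
    mu = X.mean(axis=0)
    Xs = (X - mu) / sd

    order = np.argsort(t, kind="stable")
    t, e, Xs = t[order], e[order], Xs[order]

    beta_s, cov_s, ll = _newton(t, e, Xs, variables)
    beta = beta_s / sd
    cov = cov_s / np.outer(sd, sd)
    return CoxFit(variables=variables, beta=beta, cov=cov, loglik=ll,
                  n_used=len(t), n_events=int(e.sum()),
                  times=t, events=e, X=Xs * sd + mu)


# ---------------------------------------------------------------------------
# diagnostics and corrections


def _schoenfeld_residuals(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    """Efron Schoenfeld residuals (one row per event, ordered by time) and
    the corresponding event times."""
    t, e, X = fit.times, fit.events, fit.X
    n, p = X.shape
    theta = np.exp((X - X.mean(axis=0)) @ fit.beta)
    res, res_t = [], []
    i = 0
    # risk sums recomputed per tied block (n is small when this is called)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(d_idx)
        if d:
            at_risk = slice(i, n)
            S0 = theta[at_risk].sum()
            S1 = (theta[at_risk, None] * X[at_risk]).sum(axis=0)
            t0 = theta[d_idx].sum()
            t1 = (theta[d_idx, None] * X[d_idx]).sum(axis=0)
            # Efron: average the weighted mean over the tie fractions
            xbar = np.zeros(p)
            for ell in range(d):
                f = ell / d
                xbar += (S1 - f * t1) / (S0 - f * t0)
            xbar /= d
            for k in d_idx:
                res.append(X[k] - xbar)
                res_t.append(t[k])
        i = j
    return np.asarray(res), np.asarray(res_t)


def ph_test(fit: CoxFit) -> pd.DataFrame:
    """Proportional-hazards score test per covariate plus a global test.

    Scaled Schoenfeld residuals are regressed on the event times (identity
    transform); under proportional hazards the slope is zero and the score
    statistic is chi-square with 1 df (p df for the global test).
    """
    if fit.n_events < 3:
        raise ValueError("need at least 3 events for the PH test")
    r, g = _schoenfeld_residuals(fit)
    d = len(r)
    gc = g - g.mean()
    denom_t = float((gc ** 2).sum())
    vbar = np.linalg.inv(fit.cov) / d  # average per-event information
    u = gc @ r  # sum_k (g_k - gbar) r_k, shape (p,)

    cov_u = fit.cov @ u
    rows = []
    for j, name in enumerate(fit.variables):
        # Grambsch-Therneau score statistic on the scaled residuals
        # s*_k = beta + d * cov * r_k:  [sum (g-gbar) s*_j]^2 over its
        # approximate variance d * cov_jj * sum (g-gbar)^2
        stat = d * cov_u[j] ** 2 / (fit.cov[j, j] * denom_t)
        rows.append({"variable": name, "chi2": float(stat),
                     "ph_p": float(stats.chi2.sf(stat, df=1))})
    global_stat = float(u @ np.linalg.solve(denom_t * vbar, u))
    rows.append({"variable": "GLOBAL", "chi2": global_stat,
                 "ph_p": float(stats.chi2.sf(global_stat, df=len(u)))})
    return pd.DataFrame(rows)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, m * p) per value.

    ``m`` defaults to the number of p-values supplied and must be at least
    that number.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < p.size:
        raise ValueError("family size m smaller than the number of tests")
    return np.minimum(1.0, m * p)


def logrank(groups: dict) -> tuple[float, float]:
    """Log-rank test across >= 2 groups of (months, events) arrays."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels, months, events = [], [], []
    for name, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {name!r} is empty")
        labels.extend([name] * t.size)
        months.extend(t)
        events.extend(e)
    if not any(events):
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(np.asarray(months), np.asarray(labels),
                                    np.asarray(events))
    return float(res.test_statistic), float(res.p_value)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when n_x * n_y <= 400 and the pooled sample has no
    ties; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size * y.size <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation of mid-ranks.

    p-value by exact permutation when n <= 8, otherwise the t approximation.
    Zero rank variance yields a missing rho with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need paired samples with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        warnings.warn("zero variance in ranks; rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# the screen


def _encode_adjusters(cohort: pd.DataFrame,
                      adjusters: tuple[str, ...]) -> pd.DataFrame:
    """Fixed, documented coding of the clinical covariates."""
    out = pd.DataFrame(index=cohort.index)
    for a in adjusters:
        if a == "age":
            out["age"] = pd.to_numeric(cohort["age"])
        elif a == "sex":
            out["sex_female"] = (cohort["sex"] == "female").astype(float)
        elif a == "side":
            out["side_left"] = (cohort["side"] == "left").astype(float)
        elif a == "stage":
            s = cohort["stage"].astype(str)
            if set(s.unique()) <= {"low", "high"}:
                out["stage_high"] = (s == "high").astype(float)
            else:  # I-IV coding: dichotomize I-II vs III-IV
                out["stage_high"] = s.isin(["III", "IV", "3", "4"]) \
                    .astype(float)
        elif a == "histology":
            levels = [lv for lv in ("biphasic", "sarcomatoid")
                      if (cohort["histology"] == lv).any()]
            for lv in levels:
                out[f"histology_{lv}"] = (cohort["histology"] == lv) \
                    .astype(float)
        else:
            out[a] = pd.to_numeric(cohort[a])
    return out


def run_screen(table: pd.DataFrame, cohort: pd.DataFrame,
               m: int | None = None,
               covariate_sets: dict[str, list[str]] | None = None,
               adjusters: tuple[str, ...] = DEFAULT_ADJUSTERS,
               compute_ph: bool = True,
               min_complete: int = 10) -> pd.DataFrame:
    """Univariate Cox screen over every table variable, Bonferroni-corrected,
    plus optional multivariable models with the clinical adjusters.

    ``table`` is the x1000-scaled patient variable table (index patient_id);
    ``cohort`` supplies months/event and the clinical covariates.  ``m``
    defaults to the number of screened variables and is logged in the output.
    Returns a report with columns variable, n_used, HR, ci_low, ci_high, p,
    p_corrected, ph_p, model_id, sorted by corrected p within the univariate
    block.
    """
    scale = table.attrs.get("intensity_scale")
    if scale is not None and scale == 1.0:
        raise ValueError("table is unscaled; apply scale_for_cox first")

    joined = table.join(cohort.set_index("patient_id")
                        [[c for c in cohort.columns if c != "patient_id"]],
                        how="inner")
    if len(joined.dropna(subset=["months", "event"])) < min_complete:
        raise ValueError("join produced fewer than "
                         f"{min_complete} complete cases")

    variables = list(table.columns)
    if m is None:
        m = len(variables)

    rows: list[CoxResult] = []
    for var in variables:
        sub = joined[[var, "months", "event"]].dropna()
        try:
            fit = cox_fit(sub[[var]], sub["months"], sub["event"])
        except (ValueError, ConvergenceError) as exc:
            warnings.warn(f"screen skipped {var}: {exc}", stacklevel=2)
            continue
        res = fit.results(model_id="univariate")[0]
        if compute_ph:
            res.ph_p = float(ph_test(fit)
                             .query("variable == @var")["ph_p"].iloc[0])
        rows.append(res)
    pcorr = bonferroni([r.p for r in rows], m=max(m, len(rows)))
    for r, pc in zip(rows, pcorr):
        r.p_corrected = float(pc)

    multi_rows: list[CoxResult] = []
    for model_id, markers in (covariate_sets or {}).items():
        adj = _encode_adjusters(joined, adjusters)
        design = pd.concat([joined[markers], adj], axis=1)
        sub = pd.concat([design, joined[["months", "event"]]], axis=1) \
            .dropna()
        keep = [c for c in design.columns if sub[c].std() > 0]
        dropped_cols = set(design.columns) - set(keep)
        if dropped_cols:
            warnings.warn(f"model {model_id}: dropped constant adjusters "
                          f"{sorted(dropped_cols)}", stacklevel=2)
        fit = cox_fit(sub[keep], sub["months"], sub["event"])
        results = fit.results(model_id=model_id)
        if compute_ph:
            ph = ph_test(fit).set_index("variable")["ph_p"]
            for r in results:
                r.ph_p = float(ph.get(r.variable, np.nan))
        multi_rows.extend(results)

    def _frame(results: list[CoxResult]) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in results])
        for col in ("p_corrected", "ph_p"):
            df[col] = pd.to_numeric(df[col])
        return df

    uni = _frame(rows).sort_values(["p_corrected", "p"]) \
        .reset_index(drop=True)
    report = uni
    if multi_rows:
        report = pd.concat([uni, _frame(multi_rows)], ignore_index=True)
    report.attrs["bonferroni_m"] = int(max(m, len(rows)))
    return report
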