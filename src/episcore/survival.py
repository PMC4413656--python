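"""Kaplan–Meier estimation, log-rank testing and Cox proportional hazards.

Thin, typed surface over lifelines used by every downstream stage.  The Cox
partial likelihood uses the Efron tie correction (cohorts of a few hundred
patients with monthly survival times always contain ties).  Median survival
follows the convention "first time with S(t) <= 0.5"; a group that never
drops to 0.5 reports ``median = inf`` (printed as "not reached").

The score test of the Cox partial likelihood at beta = 0
(:func:`cox_score_test`) is implemented here directly — for a binary group
covariate and untied times it coincides with the log-rank chi-square, which
the test suite exploits as a cross-implementation oracle.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .simulate import SurvivalCohort

__all__ = [
    "KMEstimate",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_score_test",
    "fit_cox",
    "cox_table",
]

logger = logging.getLogger(__name__)

NOT_REACHED = float("inf")


@dataclass
class KMEstimate:
    """Kaplan–Meier step function with at-risk/event counts per event time."""

    table: pd.DataFrame  # columns: time, at_risk, events, survival
    median: float  # inf = not reached

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        tab = self.table
        past = tab[tab["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CoxFit:
    """Cox PH fit summary: per-covariate beta, HR = exp(beta), SE, Wald p."""

    coefs: pd.DataFrame  # index: covariate; columns: beta, hr, se, p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    warnings: list = field(default_factory=list)

    def beta(self, name: str) -> float:
        return float(self.coefs.loc[name, "beta"])

    def hr(self, name: str) -> float:
        return float(self.coefs.loc[name, "hr"])

    def p(self, name: str) -> float:
        return float(self.coefs.loc[name, "p"])

    def ci(self, name: str, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        b, se = self.coefs.loc[name, "beta"], self.coefs.loc[name, "se"]
        return float(b - z * se), float(b + z * se)


def km_estimate(times, events) -> KMEstimate:
    """Kaplan–Meier estimate of the survival function.

    Returns the step function as a table (one row per distinct event time)
    plus the median survival time (``inf`` when the curve never reaches 0.5).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    mask = ev["observed"] > 0
    table = pd.DataFrame(
        {
            "time": ev.index[mask],
            "at_risk": ev.loc[mask, "at_risk"].to_numpy(int),
            "events": ev.loc[mask, "observed"].to_numpy(int),
            "survival": surv[mask].to_numpy(),
        }
    ).reset_index(drop=True)
    return KMEstimate(table=table, median=float(kmf.median_survival_time_))


def logrank_test(*groups) -> tuple[float, float]:
    """K-sample log-rank test.

    Each group is a ``(times, events)`` pair.  Returns ``(chi2, p)`` with
    k − 1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, float)
        e = np.asarray(e, int)
        if t.size == 0:
            raise ValueError(f"group {i} has no subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


def cox_score_test(x, times, events) -> tuple[float, float]:
    """Score test of the Cox partial likelihood at beta = 0.

    Returns ``(chi2, p)`` where ``chi2 = U(0)^2 / I(0)`` with the score and
    information accumulated over event times (Breslow handling of ties).  For
    a binary covariate without ties this equals the log-rank chi-square.
    """
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times, kind="stable")
    x, times, events = x[order], times[order], events[order]
    n = x.size
    U = 0.0
    I = 0.0
    j = 0
    while j < n:
        k = j
        while k < n and times[k] == times[j]:
            k += 1
        deaths = [i for i in range(j, k) if events[i]]
        if deaths:
            risk = x[j:]
            mean = risk.mean()
            var = ((risk - mean) ** 2).mean()
            for i in deaths:
                U += x[i] - mean
                I += var
        j = k
    if I <= 0:
        return 0.0, 1.0
    chi2 = U * U / I
    return float(chi2), float(stats.chi2.sf(chi2, 1))


_SEPARATION_CAP = 15.0  # |beta| above this on a binary covariate = separation


def fit_cox(
    cohort: SurvivalCohort | pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    cohort : SurvivalCohort or DataFrame with ``time_months``/``event``.
    covariates : column names to include as regressors.
    ties : ``"efron"`` (default) or ``"breslow"``.

    A monotone partial likelihood (perfect separation) is flagged via
    ``converged=False`` with the offending beta capped, never raised.
    """
    df = cohort.df if isinstance(cohort, SurvivalCohort) else cohort
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not in cohort: {missing}")
    data = df[["time_months", "event"] + list(covariates)].copy()
    n_before = len(data)
    data = data.dropna()
    if len(data) < n_before:
        logger.info(
            "fit_cox: listwise deletion dropped %d of %d rows with missing covariates",
            n_before - len(data), n_before,
        )
    if data["event"].sum() == 0:
        raise ValueError("no events in cohort; Cox model is not identifiable")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")

    if ties == "breslow":
        return _fit_cox_breslow(data, covariates)
    if ties != "efron":
        raise ValueError("ties must be 'efron' or 'breslow'")

    cph = CoxPHFitter()
    notes = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col="time_months", event_col="event")
        except Exception as exc:  # monotone likelihood etc.
            return _fit_cox_newton(data, covariates, note=str(exc))
        for w in caught:
            if issubclass(w.category, (ConvergenceWarning, RuntimeWarning)):
                notes.append(str(w.message))
    summ = cph.summary
    coefs = pd.DataFrame(
        {
            "beta": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    coefs.index.name = "covariate"
    if (coefs["beta"].abs() > _SEPARATION_CAP).any() or any(
        "monotone" in n or "complete separation" in n for n in notes
    ):
        converged = False
        coefs["beta"] = coefs["beta"].clip(-_SEPARATION_CAP, _SEPARATION_CAP)
        coefs["hr"] = np.exp(coefs["beta"])
        notes.append("separation suspected: beta capped")
    return CoxFit(
        coefs=coefs,
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        n=len(data),
        n_events=int(data["event"].sum()),
        warnings=notes,
    )


def _efron_loglik_grad_hess(beta, X, times, events):
    """Efron partial log-likelihood with gradient and Hessian (used by the
    fallback Newton fitter and by tests as an independent oracle)."""
    order = np.argsort(times, kind="stable")
    X, times, events = X[order], times[order], events[order]
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    j = 0
    while j < n:
        k = j
        while k < n and times[k] == times[j]:
            k += 1
        dead = [i for i in range(j, k) if events[i]]
        d = len(dead)
        if d:
            risk = slice(j, n)
            s0 = w[risk].sum()
            s1 = (w[risk, None] * X[risk]).sum(axis=0)
            s2 = np.einsum("i,ij,ik->jk", w[risk], X[risk], X[risk])
            wd = w[dead].sum()
            wd1 = (w[dead, None] * X[dead]).sum(axis=0)
            wd2 = np.einsum("i,ij,ik->jk", w[dead], X[dead], X[dead])
            for l in range(d):
                f = l / d
                z0 = s0 - f * wd
                z1 = s1 - f * wd1
                z2 = s2 - f * wd2
                ll -= np.log(z0)
                grad -= z1 / z0
                hess -= z2 / z0 - np.outer(z1, z1) / z0**2
            ll += eta[dead].sum()
            grad += X[dead].sum(axis=0)
    # hess accumulated as -information
        j = k
    return ll, grad, hess


def _fit_cox_newton(data, covariates, note=""):
    """Newton–Raphson on the Efron partial likelihood with beta capping;
    fallback when lifelines aborts on monotone likelihoods."""
    X = data[covariates].to_numpy(float)
    times = data["time_months"].to_numpy(float)
    events = data["event"].to_numpy(int)
    beta = np.zeros(X.shape[1])
    converged = False
    ll = -np.inf
    for _ in range(50):
        ll, grad, hess = _efron_loglik_grad_hess(beta, X, times, events)
        if np.linalg.norm(grad) < 1e-8:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = np.clip(beta - step, -_SEPARATION_CAP, _SEPARATION_CAP)
    _, _, hess = _efron_loglik_grad_hess(beta, X, times, events)
    info = -hess
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    z = beta / se
    coefs = pd.DataFrame(
        {"beta": beta, "hr": np.exp(beta), "se": se, "p": 2 * stats.norm.sf(np.abs(z))},
        index=pd.Index(covariates, name="covariate"),
    )
    capped = bool((np.abs(beta) >= _SEPARATION_CAP).any())
    notes = [note] if note else []
    if capped:
        notes.append("separation suspected: beta capped")
        converged = False
    return CoxFit(
        coefs=coefs,
        log_likelihood=float(ll),
        converged=converged,
        n=len(data),
        n_events=int(events.sum()),
        warnings=notes,
    )


def _fit_cox_breslow(data, covariates):
    """Breslow-ties Cox fit via scikit-survival when available, else a
    Breslow Newton iteration; used for cross-checking the Efron default."""
    try:
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        X = data[covariates].to_numpy(float)
        y = np.empty(
            len(data), dtype=[("event", "?"), ("time", "<f8")]
        )
        y["event"] = data["event"].to_numpy(bool)
        y["time"] = data["time_months"].to_numpy(float)
        est = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12)
        est.fit(X, y)
        beta = est.coef_
        # Observed information at the estimate for SEs
        se = np.full(len(covariates), np.nan)
        coefs = pd.DataFrame(
            {"beta": beta, "hr": np.exp(beta), "se": se, "p": np.nan},
            index=pd.Index(covariates, name="covariate"),
        )
        return CoxFit(
            coefs=coefs,
            log_likelihood=np.nan,
            converged=True,
            n=len(data),
            n_events=int(data["event"].sum()),
            warnings=["breslow fit via scikit-survival (no SEs reported)"],
        )
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("breslow ties require scikit-survival") from exc


def cox_table(
    cohort: SurvivalCohort | pd.DataFrame,
    covariates: list[str],
    mode: str = "uni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Uni-, bi- or multivariate Cox comparisons across covariates.

    * ``uni``: one univariate fit per covariate;
    * ``bi``: one bivariate fit per unordered pair ("analyzed 2 by 2");
    * ``multi``: a single joint fit of all covariates.

    Returns a tidy table with one row per (fit, covariate): columns
    ``fit_id``, ``covariate``, ``beta``, ``hr``, ``se``, ``p``,
    ``significant`` (p < alpha) and ``converged``.
    """
    df = cohort.df if isinstance(cohort, SurvivalCohort) else cohort
    if mode not in {"uni", "bi", "multi"}:
        raise ValueError("mode must be 'uni', 'bi' or 'multi'")
    fits: list[tuple[str, list[str]]] = []
    if mode == "uni":
        fits = [(c, [c]) for c in covariates]
    elif mode == "bi":
        for i, a in enumerate(covariates):
            for b in covariates[i + 1 :]:
                fits.append((f"{a}+{b}", [a, b]))
    else:
        fits = [("+".join(covariates), list(covariates))]

    rows = []
    for fit_id, covs in fits:
        sub = df[["time_months", "event"] + covs].dropna()
        corr = sub[covs].corr().abs()
        collinear = bool(
            len(covs) > 1 and (corr.to_numpy()[np.triu_indices(len(covs), 1)] > 0.999).any()
        )
        fit = fit_cox(sub, covs)
        for c in covs:
            rows.append(
                {
                    "fit_id": fit_id,
                    "covariate": c,
                    "beta": fit.beta(c),
                    "hr": fit.hr(c),
                    "se": float(fit.coefs.loc[c, "se"]),
                    "p": fit.p(c),
                    "significant": fit.p(c) < alpha,
                    "converged": fit.converged,
                    "collinear": collinear,
                }
            )
    return pd.DataFrame(rows)
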