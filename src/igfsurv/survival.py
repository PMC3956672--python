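"""Survival statistics: Kaplan-Meier, log-rank, Cox proportional hazards.

Thin, strongly-typed wrappers over ``lifelines`` (product-limit estimation,
log-rank testing) and ``statsmodels`` ``PHReg`` (partial-likelihood Cox
models with Efron or Breslow tie handling), plus the model-building
procedures the pipeline needs: backward elimination at a configurable
retention level and Wald interaction tests on a product term.

Times are in months throughout; events are 0/1 with 1 = event observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from igfsurv import constants


# --------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance."""

    times: np.ndarray          # distinct event times (months), increasing
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    n_events: np.ndarray       # events at each time
    greenwood_var: np.ndarray  # Var[S(t)] by Greenwood's formula
    n: int

    def rate_at(self, t: float) -> float:
        """Survival probability at time ``t`` (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def km_fit(time, event) -> KMCurve:
    """Kaplan-Meier estimate of the survival function of one group."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("km_fit requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    times = table.index.to_numpy(dtype=float)[mask]
    at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    d = table["observed"].to_numpy(dtype=float)[mask]
    surv = np.asarray(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in times]
    )
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (at_risk * (at_risk - d))
    terms[~np.isfinite(terms)] = np.nan
    gvar = surv**2 * np.nancumsum(terms)
    return KMCurve(times, surv, at_risk, d, gvar, n=int(time.size))


# --------------------------------------------------------------------------
# Log-rank


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    n_groups: int


def logrank_test(time, event, group) -> LogrankResult:
    """Unweighted k-sample log-rank test (chi-square, k-1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test requires at least two non-empty groups")
    if event.sum() < 1:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(time, group, event)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(labels) - 1,
        n_groups=len(labels),
    )


# --------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """A fitted Cox model: one row per covariate in ``summary``.

    ``summary`` columns: coef (log hazard ratio), se, hr, ci_lower,
    ci_upper, z, p (Wald).
    """

    summary: pd.DataFrame
    ties: str
    converged: bool
    n: int
    n_events: int
    log_likelihood: float = np.nan
    cov_params: np.ndarray | None = field(default=None, repr=False)
    notes: str = ""

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def cox_fit(time, event, covariates: pd.DataFrame, ties: str = "efron") -> CoxFit:
    """Maximize the Cox partial likelihood and report Wald inference.

    Parameters
    ----------
    time, event : array-like
        Follow-up in months and 0/1 event flags.
    covariates : DataFrame
        Numeric design matrix; no constant column allowed.
    ties : {"efron", "breslow"}
        Tie-handling method; Efron is the default.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method: {ties}")
    X = covariates.astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n_events = int(event.sum())
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant: no contrast")
    if n_events < X.shape[1]:
        raise ValueError(
            f"{n_events} events for {X.shape[1]} covariates: model refused"
        )

    converged = True
    notes = ""
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if ties == "efron":
                frame = X.copy()
                frame["__t"] = time
                frame["__e"] = event
                cph = CoxPHFitter()
                cph.fit(
                    frame,
                    duration_col="__t",
                    event_col="__e",
                    # tight stopping rule: lifelines' default relative
                    # log-likelihood stop leaves ~1e-6 coefficient error
                    fit_options={"precision": 1e-12, "r_precision": 0.0},
                )
                coef = cph.params_.to_numpy(dtype=float)
                se = cph.standard_errors_.to_numpy(dtype=float)
                llf = float(cph.log_likelihood_)
                cov = np.asarray(cph.variance_matrix_)
            else:
                res = PHReg(time, X.to_numpy(), status=event, ties=ties).fit(disp=False)
                coef = np.asarray(res.params, dtype=float)
                se = np.asarray(res.bse, dtype=float)
                llf = float(res.llf)
                cov = np.asarray(res.cov_params())
        for w in caught:
            if "onverg" in str(w.message):
                converged = False
                notes = str(w.message)
    except Exception as exc:  # separation, singular information, ...
        nan = np.full(X.shape[1], np.nan)
        summary = pd.DataFrame(
            {"coef": nan, "se": nan, "hr": nan, "ci_lower": nan,
             "ci_upper": nan, "z": nan, "p": nan},
            index=list(X.columns),
        )
        return CoxFit(summary, ties, False, len(time), n_events, notes=str(exc))
    if not np.all(np.isfinite(coef)) or np.any(np.abs(coef) > 50):
        converged = False
        notes = notes or "diverging coefficient (possible separation)"
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_lower": np.exp(coef - zcrit * se),
            "ci_upper": np.exp(coef + zcrit * se),
            "z": z,
            "p": p,
        },
        index=list(X.columns),
    )
    return CoxFit(
        summary,
        ties,
        converged,
        n=len(time),
        n_events=n_events,
        log_likelihood=llf,
        cov_params=cov,
        notes=notes,
    )


def _block_wald_p(fit: CoxFit, columns: list[str]) -> float:
    """Wald chi-square p-value for a block of coefficients jointly zero."""
    idx = [list(fit.summary.index).index(c) for c in columns]
    b = fit.summary["coef"].to_numpy()[idx]
    V = fit.cov_params[np.ix_(idx, idx)]
    try:
        w = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return np.nan
    return float(stats.chi2.sf(w, df=len(idx)))


def multivariate_model(
    time,
    event,
    covariates: pd.DataFrame,
    combined_variable: str,
    blocks: dict[str, list[str]] | None = None,
    alpha_stay: float = constants.ALPHA_STAY_MULTIVARIATE,
    ties: str = "efron",
) -> tuple[CoxFit, list[str]]:
    """Backward elimination keeping covariates with Wald p < ``alpha_stay``.

    The combined biomarker variable is always retained; the clinical
    candidate covariates are eliminated one block at a time (a block is a
    categorical covariate's dummy set), dropping the least significant block
    each round until every remaining block satisfies the retention level.

    Returns the final fit and the names of the retained blocks.
    """
    if combined_variable not in covariates.columns:
        raise ValueError(f"combined variable {combined_variable!r} not in design")
    if blocks is None:
        blocks = {c: [c] for c in covariates.columns if c != combined_variable}
    for name, cols in blocks.items():
        missing = [c for c in cols if c not in covariates.columns]
        if missing:
            raise ValueError(f"block {name!r} references unknown columns {missing}")

    active = dict(blocks)
    while True:
        cols = [combined_variable] + [c for b in active.values() for c in b]
        fit = cox_fit(time, event, covariates[cols], ties=ties)
        if not fit.converged or not active:
            break
        pvals = {name: _block_wald_p(fit, b) for name, b in active.items()}
        worst = max(pvals, key=lambda k: (np.inf if np.isnan(pvals[k]) else pvals[k]))
        worst_p = pvals[worst]
        if np.isnan(worst_p) or worst_p >= alpha_stay:
            del active[worst]
            if not active:
                fit = cox_fit(time, event, covariates[[combined_variable]], ties=ties)
                break
        else:
            break
    return fit, list(active)


def interaction_test(time, event, cluster, group, ties: str = "efron") -> dict:
    """Wald test of effect modification: cluster x group product term.

    Both inputs must be binary 0/1; returns the p-value of the product
    coefficient plus the full fit.
    """
    cluster = np.asarray(cluster, dtype=float)
    group = np.asarray(group, dtype=float)
    if np.unique(cluster).size < 2:
        raise ValueError("cluster variable is constant: no contrast")
    if np.unique(group).size < 2:
        raise ValueError("group variable is constant: no contrast")
    tab = pd.crosstab(cluster, group)
    if (tab.to_numpy() == 0).any():
        warnings.warn("empty cell in the cluster x group cross-classification")
    X = pd.DataFrame(
        {"cluster": cluster, "group": group, "cluster_x_group": cluster * group}
    )
    fit = cox_fit(time, event, X, ties=ties)
    return {
        "p_interaction": fit.p("cluster_x_group"),
        "coef_interaction": float(fit.summary.loc["cluster_x_group", "coef"]),
        "fit": fit,
    }


def four_year_rate(time, event) -> float:
    """Kaplan-Meier survival probability at 48 months."""
    return km_fit(time, event).rate_at(constants.FOUR_YEAR_MONTHS)
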