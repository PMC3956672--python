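"""Independent brute-force reference implementations used only by tests.

These deliberately avoid lifelines/statsmodels code paths: Kaplan-Meier and
log-rank are computed from first principles on explicit risk-set tables, and
the Cox partial likelihood is written out directly and maximized with a
generic scipy optimizer.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def km_brute_force(time, event):
    """Product-limit estimate via explicit risk-set enumeration.

    Returns (event_times, survival) at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ts = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in ts:
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return ts, np.array(surv)


def logrank_brute_force(time, event, group):
    """Two-group unweighted log-rank chi-square via O-E tables."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    g1 = group == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return float(chi2)


def _efron_neg_log_partial_likelihood(beta, time, event, X):
    beta = np.atleast_1d(beta)
    eta = X @ beta
    risk = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = int(D.sum())
        sum_risk_R = risk[R].sum()
        sum_risk_D = risk[D].sum()
        ll += eta[D].sum()
        for j in range(d):
            ll -= np.log(sum_risk_R - (j / d) * sum_risk_D)
    return -ll


def cox_brute_force(time, event, X, ties: str = "efron"):
    """Maximize the Cox partial likelihood with a generic optimizer."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    assert ties == "efron"
    res = optimize.minimize(
        _efron_neg_log_partial_likelihood,
        x0=np.zeros(X.shape[1]),
        args=(time, event, X),
        method="BFGS",
        options={"gtol": 1e-10},
    )
    return res.x
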