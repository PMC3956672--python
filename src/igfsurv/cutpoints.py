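"""Biomarker cut-point candidates and stability validation.

Dichotomizing a continuous or ordinal biomarker at a data-driven cut-off is
prone to false positives (the minimum-p-value problem).  This module
implements the defence used in the analysis:

1. candidate cut-offs restricted to quartiles (plus a 9-decile log-rank scan
   for over-dispersed scores, for visual selection only);
2. repeated stratified train/validation splitting: the training median is
   applied to the held-out half, hazard ratios are estimated in both halves,
   and a candidate is accepted only when the validation-set confidence
   intervals do not systematically cross a hazard ratio of 1;
3. the final pre-defined cut-off is the median over replications of the
   per-replication training medians ("median of medians").

Quantile conventions: medians use the averaging convention; quartiles and
deciles of coarse ordinal scores use lower interpolation so that every
candidate is an attainable score value (the dichotomization rule is
"high when score >= cut-off").  Both are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from igfsurv.cohort import Cohort
from igfsurv.survival import cox_fit, logrank_test


# --------------------------------------------------------------------------
# Candidates


@dataclass
class CutoffCandidateSet:
    marker: str
    candidates: list[tuple[str, float]]  # (name, value), nondecreasing in value
    degenerate: bool = False


def quantile_candidates(
    scores, marker: str = "", quartile_method: str = "lower"
) -> CutoffCandidateSet:
    """First quartile, median and third quartile of the observed scores.

    The median averages the two central order statistics for even n; the
    quartiles use the given interpolation (default "lower", appropriate for
    coarse ordinal scores).
    """
    x = pd.Series(scores, dtype=float).dropna().to_numpy()
    if x.size < 4:
        raise ValueError("need at least 4 non-missing scores for quartiles")
    q1 = float(np.quantile(x, 0.25, method=quartile_method))
    med = float(np.median(x))
    q3 = float(np.quantile(x, 0.75, method=quartile_method))
    degenerate = len({q1, med, q3}) < 3
    if degenerate:
        warnings.warn(
            f"degenerate score distribution for {marker or 'marker'}: "
            "quartile candidates collapse"
        )
    return CutoffCandidateSet(
        marker=marker,
        candidates=[("Q1", q1), ("median", med), ("Q3", q3)],
        degenerate=degenerate,
    )


@dataclass
class DecileScanResult:
    marker: str
    deciles: pd.DataFrame  # columns: decile, cut, p_dfs, p_os
    argmin_dfs: int | None
    argmin_os: int | None
    note: str = (
        "Minimum p over 9 data-driven cuts is not a valid single test; "
        "no multiplicity adjustment is applied here. The scan informs a "
        "visual choice among pre-specified quantile candidates only."
    )


def decile_scan(scores, endpoints: dict[str, tuple], marker: str = "") -> DecileScanResult:
    """Log-rank p-values of the high/low split at each of the 9 deciles.

    ``endpoints`` maps endpoint name ("dfs"/"os") to ``(time, event)``
    arrays.  A decile cut that leaves one arm empty records a missing p for
    that decile.  The scan reports all nine cuts plus the location of the
    minimum; it never auto-selects a final cut-off.
    """
    x = pd.Series(scores, dtype=float)
    obs = x.notna().to_numpy()
    xv = x[obs].to_numpy()
    rows = []
    for k in range(1, 10):
        cut = float(np.quantile(xv, k / 10.0, method="lower"))
        high = xv >= cut
        row: dict = {"decile": k, "cut": cut}
        for name, (time, event) in endpoints.items():
            t = np.asarray(time, dtype=float)[obs]
            e = np.asarray(event, dtype=int)[obs]
            if high.all() or (~high).all() or e.sum() == 0:
                row[f"p_{name}"] = np.nan
            else:
                row[f"p_{name}"] = logrank_test(t, e, high.astype(int)).p_value
        rows.append(row)
    table = pd.DataFrame(rows)
    out_argmin = {}
    for name in endpoints:
        col = table[f"p_{name}"]
        out_argmin[name] = (
            int(table.loc[col.idxmin(), "decile"]) if col.notna().any() else None
        )
    return DecileScanResult(
        marker=marker,
        deciles=table,
        argmin_dfs=out_argmin.get("dfs"),
        argmin_os=out_argmin.get("os"),
    )


# --------------------------------------------------------------------------
# Stratified splitting


def stratified_split(
    cohort_df: pd.DataFrame,
    ratio: float,
    strata: list[str],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly partition rows into training/validation, balanced per stratum.

    Within every cell of the strata cross-classification the training count
    differs from ``ratio * cell size`` by less than 1 (fractional remainders
    are resolved by a Bernoulli draw); singleton cells are assigned at
    random.  Returns positional index arrays (training, validation).
    """
    if not 0 < ratio < 1:
        raise ValueError(f"split ratio must be in (0, 1): {ratio}")
    missing = [c for c in strata if c not in cohort_df.columns]
    if missing:
        raise ValueError(f"strata columns not in cohort: {missing}")
    rng = np.random.default_rng(seed)
    n = len(cohort_df)
    keys = (
        cohort_df[strata].astype(str).agg("|".join, axis=1)
        if strata
        else pd.Series([""] * n, index=cohort_df.index)
    )
    train_mask = np.zeros(n, dtype=bool)
    positions = np.arange(n)
    for _, cell in pd.Series(positions).groupby(keys.to_numpy()):
        idx = cell.to_numpy()
        rng.shuffle(idx)
        target = len(idx) * ratio
        k = int(np.floor(target))
        if rng.random() < target - k:
            k += 1
        k = min(k, len(idx))
        train_mask[idx[:k]] = True
    train = positions[train_mask]
    valid = positions[~train_mask]
    return train, valid


# --------------------------------------------------------------------------
# Internal cross-validation


@dataclass
class CutoffCVReport:
    """Stability evidence for one marker/endpoint cut-off candidate."""

    marker: str
    endpoint: str
    quantile: float
    n_replications: int
    replications: pd.DataFrame = field(repr=False)
    # columns: replication, cutoff, hr_train, ci_low_train, ci_high_train,
    #          hr_valid, ci_low_valid, ci_high_valid
    final_cutoff: float = np.nan
    pct_valid_ci_crossing_1: float = np.nan
    mean_hr_diff: float = np.nan
    median_hr_diff: float = np.nan
    mean_log_hr_diff: float = np.nan
    median_log_hr_diff: float = np.nan
    n_nonconverged: int = 0

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "endpoint": self.endpoint,
            "quantile": self.quantile,
            "n_replications": self.n_replications,
            "final_cutoff": self.final_cutoff,
            "pct_valid_ci_crossing_1": self.pct_valid_ci_crossing_1,
            "mean_hr_diff": self.mean_hr_diff,
            "median_hr_diff": self.median_hr_diff,
            "mean_log_hr_diff": self.mean_log_hr_diff,
            "median_log_hr_diff": self.median_log_hr_diff,
            "n_nonconverged": self.n_nonconverged,
        }


def _train_quantile(x: np.ndarray, q: float, quartile_method: str) -> float:
    if q == 0.5:
        return float(np.median(x))
    return float(np.quantile(x, q, method=quartile_method))


def internal_cross_validation(
    cohort: Cohort | pd.DataFrame,
    scores,
    endpoint_time,
    endpoint_event,
    marker: str = "",
    endpoint: str = "",
    n_replications: int = 100,
    ratio: float = 0.5,
    strata: list[str] | None = None,
    seed: int = 0,
    quantile: float = 0.5,
    quartile_method: str = "lower",
    fit_models: bool = True,
    adjust_columns: list[str] | None = None,
) -> CutoffCVReport:
    """Repeated stratified-split validation of a quantile cut-off.

    For each replication: split the cohort, compute the requested training
    quantile (median by default) of the marker scores, dichotomize both
    halves at it (high when score >= cut-off), fit a proportional-hazards
    model of the dichotomized marker in each half, and record hazard ratios
    with 95% confidence intervals.  Patients with a missing score are
    excluded from the model fits of that replication only.

    Per-replication seeds are spawned deterministically from ``seed``; the
    final cut-off is the median of the per-replication training quantiles.
    Non-convergent fits are recorded as missing and counted, never imputed.
    Set ``fit_models=False`` to compute cut-offs only (no hazard ratios).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    scores = pd.Series(np.asarray(scores, dtype=float), index=df.index)
    time = np.asarray(endpoint_time, dtype=float)
    event = np.asarray(endpoint_event, dtype=int)
    strata = strata or []
    adjust_columns = adjust_columns or []

    child_seeds = np.random.SeedSequence(seed).generate_state(n_replications) % (2**31)
    rows = []
    n_nonconv = 0
    for r in range(n_replications):
        tr, va = stratified_split(df, ratio, strata, int(child_seeds[r]))
        x_tr = scores.iloc[tr].dropna().to_numpy()
        cut = _train_quantile(x_tr, quantile, quartile_method)
        row = {"replication": r, "cutoff": cut}
        if fit_models:
            for name, idx in (("train", tr), ("valid", va)):
                s = scores.iloc[idx]
                ok = s.notna().to_numpy()
                high = (s[ok] >= cut).astype(float).to_numpy()
                t, e = time[idx][ok], event[idx][ok]
                hr = lo = hi = np.nan
                if 0 < high.sum() < high.size and e.sum() >= 1:
                    X = pd.DataFrame({"high": high})
                    for c in adjust_columns:
                        X[c] = df[c].to_numpy(dtype=float)[idx][ok]
                    try:
                        fit = cox_fit(t, e, X)
                        if fit.converged:
                            hr = fit.hr("high")
                            lo, hi = fit.ci("high")
                        else:
                            n_nonconv += 1
                    except ValueError:
                        n_nonconv += 1
                row[f"hr_{name}"] = hr
                row[f"ci_low_{name}"] = lo
                row[f"ci_high_{name}"] = hi
        rows.append(row)

    reps = pd.DataFrame(rows)
    report = CutoffCVReport(
        marker=marker,
        endpoint=endpoint,
        quantile=quantile,
        n_replications=n_replications,
        replications=reps,
        final_cutoff=float(np.median(reps["cutoff"])),
    )
    if fit_models:
        crossing = (reps["ci_low_valid"] <= 1.0) & (reps["ci_high_valid"] >= 1.0)
        valid_ok = reps["hr_valid"].notna()
        if valid_ok.any():
            report.pct_valid_ci_crossing_1 = float(
                100.0 * crossing[valid_ok].mean()
            )
        diff = reps["hr_train"] - reps["hr_valid"]
        ldiff = np.log(reps["hr_train"]) - np.log(reps["hr_valid"])
        report.mean_hr_diff = float(diff.mean())
        report.median_hr_diff = float(diff.median())
        report.mean_log_hr_diff = float(ldiff.mean())
        report.median_log_hr_diff = float(ldiff.median())
        report.n_nonconverged = n_nonconv
    return report


# --------------------------------------------------------------------------
# Candidate acceptance


@dataclass
class CandidateDecision:
    accepted: bool
    rationale: str
    pct_ci_crossing_1: float
    median_hr_valid: float


def validate_candidate(
    report: CutoffCVReport,
    max_pct_crossing: float = 80.0,
    null_hr_band: tuple[float, float] = (0.8, 1.25),
) -> CandidateDecision:
    """Judge whether a cut-off candidate is independently prognostic.

    Default rule (configurable): reject when the validation-set confidence
    interval crosses HR = 1 in more than ``max_pct_crossing`` percent of
    replications AND the median validation hazard ratio sits inside the
    ``null_hr_band`` (estimates oscillating around 1).  The evidence is
    always returned so callers can apply their own rule.
    """
    if report.replications.empty or "hr_valid" not in report.replications:
        raise ValueError("empty or model-free cross-validation report")
    hr_valid = report.replications["hr_valid"].dropna()
    if hr_valid.empty:
        raise ValueError("no convergent validation fits in report")
    med = float(hr_valid.median())
    pct = report.pct_valid_ci_crossing_1
    oscillates = null_hr_band[0] <= med <= null_hr_band[1]
    if pct > max_pct_crossing and oscillates:
        return CandidateDecision(
            accepted=False,
            rationale=(
                f"not independently prognostic: {pct:.0f}% of validation CIs "
                f"cross HR = 1 and the median validation HR ({med:.3f}) "
                "oscillates around 1"
            ),
            pct_ci_crossing_1=pct,
            median_hr_valid=med,
        )
    return CandidateDecision(
        accepted=True,
        rationale=(
            f"candidate retained: {pct:.0f}% of validation CIs cross HR = 1; "
            f"median validation HR {med:.3f}"
        ),
        pct_ci_crossing_1=pct,
        median_hr_valid=med,
    )
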