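"""Synthetic cohort generator for node-positive early breast cancer.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without patient-level
data:

* a five-class immunophenotype mixture (luminal A/B, luminal-HER2,
  HER2-enriched, triple-negative) with configurable proportions;
* subtype-dependent ordinal IHC marker marginals (IRS categories for
  IGF1R-alpha/beta and IGF2R, intensity-band levels for IGFBP2, positivity
  for EGFR) coupled through a latent Gaussian copula, so marginal
  frequencies and pairwise associations are independently controllable;
* clinicopathological covariates drawn from cohort-level marginal
  frequencies;
* coupled relapse / death event times from a proportional-hazards model:
  a relapse process and a death process share one linear predictor, DFS is
  the earlier of the two and OS is the death time, so DFS time <= OS time
  by construction and BOTH endpoints are exactly proportional-hazards in
  the configured coefficients; administrative censoring at a fixed horizon
  plus uniform random dropout.

Default parameters reproduce a cohort of 1,021 women with the subtype mix,
covariate frequencies, marker positivity pattern (IGF1R-alpha enriched in
hormone-receptor-positive tumors, IGF2R and EGFR in receptor-negative
tumors) and event rates (4-year DFS ~76%, 4-year OS ~90%) of a typical
adjuvant-trial population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from igfsurv.cohort import Cohort

SUBTYPE_ORDER = (
    "luminal_A", "luminal_B", "luminal_HER2", "HER2_enriched", "triple_negative",
)

#: markers coupled through the latent Gaussian copula, in matrix order
COPULA_MARKERS = ("IGF1Ra", "IGF1Rb", "IGF2R", "IGFBP2", "EGFR")

#: attainable IRS values and a canonical (SI, PP) pair realizing each
IRS_CATEGORIES = ((0, 0, 0), (1, 1, 1), (2, 1, 2), (3, 1, 3), (4, 2, 2), (6, 2, 3), (9, 3, 3))

#: IGFBP2 staining levels as canonical (weak%, moderate%, strong%) triples
IGFBP2_LEVELS = (
    (0.0, 0.0, 0.0),      # H = 0
    (30.0, 5.0, 0.0),     # H = 40
    (40.0, 15.0, 0.0),    # H = 70
    (30.0, 30.0, 10.0),   # H = 120
    (20.0, 40.0, 20.0),   # H = 160
    (10.0, 30.0, 50.0),   # H = 220
    (5.0, 25.0, 70.0),    # H = 265
)

_LUMINAL_IRS_A = (0.20, 0.15, 0.25, 0.10, 0.12, 0.10, 0.08)
_HRNEG_IRS_A_HER2 = (0.40, 0.25, 0.185, 0.06, 0.05, 0.035, 0.02)
_HRNEG_IRS_A_TN = (0.38, 0.25, 0.189, 0.07, 0.05, 0.039, 0.022)
_IRS_B = (0.668, 0.12, 0.10, 0.05, 0.03, 0.02, 0.012)
_LUMINAL_IRS_2R = (0.50, 0.15, 0.15, 0.08, 0.06, 0.04, 0.02)
_HRNEG_IRS_2R = (0.35, 0.15, 0.18, 0.12, 0.10, 0.06, 0.04)
_IGFBP2_DEFAULT = (0.15, 0.12, 0.13, 0.20, 0.18, 0.14, 0.08)
_IGFBP2_TN = (0.35, 0.20, 0.15, 0.12, 0.10, 0.05, 0.03)


def default_marker_marginals() -> dict:
    """Per-subtype category probabilities for the copula-coupled markers.

    IGF1R-alpha is enriched in hormone-receptor-positive subtypes and scarce
    in HER2-enriched / triple-negative tumors; IGF1R-beta is absent (IRS 0)
    in about two thirds of tumors everywhere; IGF2R is shifted upward in
    receptor-negative tumors; IGFBP2 is depressed in triple-negative tumors;
    EGFR positivity concentrates in triple-negative and HER2-enriched tumors.
    """
    m = {}
    for st in SUBTYPE_ORDER:
        luminal = st.startswith("luminal")
        m[st] = {
            "IGF1Ra": _LUMINAL_IRS_A if luminal else (
                _HRNEG_IRS_A_HER2 if st == "HER2_enriched" else _HRNEG_IRS_A_TN
            ),
            "IGF1Rb": _IRS_B,
            "IGF2R": _LUMINAL_IRS_2R if luminal else _HRNEG_IRS_2R,
            "IGFBP2": _IGFBP2_TN if st == "triple_negative" else _IGFBP2_DEFAULT,
            "EGFR": {
                "luminal_A": (0.94, 0.06),
                "luminal_B": (0.92, 0.08),
                "luminal_HER2": (0.91, 0.09),
                "HER2_enriched": (0.645, 0.355),
                "triple_negative": (0.378, 0.622),
            }[st],
        }
    return m


def default_marker_correlation() -> np.ndarray:
    """Latent correlation among (IGF1Ra, IGF1Rb, IGF2R, IGFBP2, EGFR).

    Qualitative pattern: the IGF1R-axis markers (alpha, beta, IGFBP2)
    associate positively with each other, IGF2R associates inversely with
    all of them, and EGFR weakly inversely with the axis.
    """
    return np.array(
        [
            [1.00, 0.45, -0.35, 0.30, -0.15],
            [0.45, 1.00, -0.25, 0.25, -0.10],
            [-0.35, -0.25, 1.00, -0.20, 0.15],
            [0.30, 0.25, -0.20, 1.00, -0.10],
            [-0.15, -0.10, 0.15, -0.10, 1.00],
        ]
    )


def default_covariate_frequencies() -> dict:
    return {
        "menopause": {"pre": 0.464, "post": 0.536},
        "nodes": {"0": 0.004, "1-3": 0.390, "ge4": 0.606},
        "size": {"le2cm": 0.308, "gt2cm": 0.692},
        "grade": {"I-II": 0.496, "III": 0.504},
        "histology": {"mixed": 0.072, "ductal": 0.776, "lobular": 0.102, "other": 0.050},
        "surgery": {"MRM": 0.686, "BCS": 0.314},
        "radiotherapy": {"yes": 0.756, "no": 0.214, None: 0.030},
        "hormonotherapy": {"yes": 0.778, "no": 0.200, None: 0.022},
        "taxane": {"yes": 0.80, "no": 0.20},
    }


def default_log_hazard_coefficients() -> dict:
    """Log hazard ratios applied to relapse and death processes.

    Keys name binary indicators: clinicopathological (``nodes_ge4``,
    ``surgery_BCS``, ``grade_III``) and the two true pathway-cluster
    memberships.  The default cluster effect is log(0.55), the magnitude of
    a clinically meaningful protective combined-biomarker effect.
    """
    return {
        "nodes_ge4": float(np.log(2.0)),
        "surgery_BCS": float(np.log(0.60)),
        "grade_III": float(np.log(1.5)),
        "cluster_igf1ra_high_igf2r_low": float(np.log(0.55)),
        "cluster_igf1ra_high_egfr_neg": 0.0,
    }


@dataclass
class SimulationConfig:
    """Everything :func:`generate_cohort` needs, with realistic defaults."""

    n_patients: int = 1021
    # defaults are the exact subtype counts of a 1,021-patient reference
    # cohort (252 / 394 / 137 / 109 / 129), i.e. 24.6/38.6/13.4/10.6/12.6%
    subtype_proportions: dict = field(
        default_factory=lambda: dict(
            zip(SUBTYPE_ORDER, (252 / 1021, 394 / 1021, 137 / 1021, 109 / 1021, 129 / 1021))
        )
    )
    marker_marginals: dict = field(default_factory=default_marker_marginals)
    marker_correlation: np.ndarray = field(default_factory=default_marker_correlation)
    log_hazard_coefficients: dict = field(default_factory=default_log_hazard_coefficients)
    # per-month baseline hazards; calibrated to ~76% 4-year DFS / ~90% 4-year OS
    baseline_hazard: dict = field(
        default_factory=lambda: {
            "family": "exponential",
            "relapse": 0.0022,
            "death": 0.0015,
            "shape": 1.0,  # used by the weibull family
        }
    )
    censoring: dict = field(
        default_factory=lambda: {"horizon_months": 166.7, "dropout_rate": 0.50}
    )
    covariate_frequencies: dict = field(default_factory=default_covariate_frequencies)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        props = np.array([self.subtype_proportions[s] for s in SUBTYPE_ORDER])
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("subtype proportions must be nonnegative and sum to 1")
        R = np.asarray(self.marker_correlation, dtype=float)
        if R.shape != (len(COPULA_MARKERS),) * 2:
            raise ValueError(f"correlation matrix must be {len(COPULA_MARKERS)}x{len(COPULA_MARKERS)}")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semidefinite")
        for st in SUBTYPE_ORDER:
            for mk in COPULA_MARKERS:
                p = np.asarray(self.marker_marginals[st][mk], dtype=float)
                if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                    raise ValueError(
                        f"marginal for {mk} in {st} must be a probability vector"
                    )
        if self.baseline_hazard["family"] not in ("exponential", "weibull"):
            raise ValueError("baseline hazard family must be exponential or weibull")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        # a cluster effect can never be realized if its subtypes have mass 0
        lum_ab = self.subtype_proportions["luminal_A"] + self.subtype_proportions["luminal_B"]
        for key, beta in self.log_hazard_coefficients.items():
            if key.startswith("cluster_") and beta != 0.0 and lum_ab == 0.0:
                warnings.warn(
                    f"coefficient {key!r} is nonzero but the luminal A+B "
                    "proportion is zero; the effect cannot be expressed"
                )


@dataclass
class SyntheticCohort:
    cohort: Cohort
    truth: dict = field(repr=False)


def population_irs_median(config: SimulationConfig, marker: str) -> float:
    """Theoretical median of a marker's IRS mixture distribution."""
    values = np.array([c[0] for c in IRS_CATEGORIES], dtype=float)
    probs = np.zeros(len(values))
    for st in SUBTYPE_ORDER:
        probs += config.subtype_proportions[st] * np.asarray(
            config.marker_marginals[st][marker], dtype=float
        )
    cdf = np.cumsum(probs)
    return float(values[np.searchsorted(cdf, 0.5)])


def _draw_categorical(rng, freq: dict, n: int) -> np.ndarray:
    keys = list(freq)
    p = np.array([freq[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return np.array([keys[i] for i in idx], dtype=object)


def _sample_times(rng, rate: float, eta: np.ndarray, family: str, shape: float) -> np.ndarray:
    """Event times under h(t) = h0(t) exp(eta)."""
    e = rng.exponential(1.0, size=eta.size)  # unit exponentials
    if family == "exponential":
        return e / (rate * np.exp(eta))
    # weibull with H0(t) = (rate * t)^shape
    return (e / np.exp(eta)) ** (1.0 / shape) / rate


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; deterministic given the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    props = np.array([config.subtype_proportions[s] for s in SUBTYPE_ORDER])
    subtype = np.array(SUBTYPE_ORDER, dtype=object)[
        rng.choice(len(SUBTYPE_ORDER), size=n, p=props)
    ]

    cov = {}
    for name, freq in config.covariate_frequencies.items():
        cov[name] = _draw_categorical(rng, freq, n)
    age = np.clip(np.round(rng.normal(52.7, 10.0, size=n), 1), 22.0, 79.0)

    # latent Gaussian copula across the IGF-pathway markers and EGFR
    R = np.asarray(config.marker_correlation, dtype=float)
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    Z = rng.standard_normal((n, len(COPULA_MARKERS))) @ L.T
    U = stats.norm.cdf(Z)

    category = np.zeros((n, len(COPULA_MARKERS)), dtype=int)
    for j, mk in enumerate(COPULA_MARKERS):
        for st in SUBTYPE_ORDER:
            mask = subtype == st
            if not mask.any():
                continue
            p = np.asarray(config.marker_marginals[st][mk], dtype=float)
            cdf = np.cumsum(p)
            cdf[-1] = 1.0
            category[mask, j] = np.searchsorted(cdf, U[mask, j], side="left")

    irs_values = np.array([c[0] for c in IRS_CATEGORIES])
    si_values = np.array([c[1] for c in IRS_CATEGORIES])
    pp_values = np.array([c[2] for c in IRS_CATEGORIES])
    cols: dict = {"patient_id": [f"P{i + 1:05d}" for i in range(n)], "age_years": age}
    cols.update(cov)
    for mk in ("IGF1Ra", "IGF1Rb", "IGF2R"):
        j = COPULA_MARKERS.index(mk)
        cols[f"{mk}_SI"] = si_values[category[:, j]]
        cols[f"{mk}_PP"] = pp_values[category[:, j]]
    jb = COPULA_MARKERS.index("IGFBP2")
    bands = np.array(IGFBP2_LEVELS)[category[:, jb]]
    cols["IGFBP2_weak_pct"] = bands[:, 0]
    cols["IGFBP2_moderate_pct"] = bands[:, 1]
    cols["IGFBP2_strong_pct"] = bands[:, 2]

    je = COPULA_MARKERS.index("EGFR")
    egfr_pos = category[:, je] == 1
    egfr_pct = np.zeros(n)
    egfr_pct[egfr_pos] = rng.integers(1, 96, size=int(egfr_pos.sum())).astype(float)
    cols["EGFR_pct"] = egfr_pct

    # classifier markers, consistent with the drawn subtype
    er_pct = np.zeros(n)
    pgr_pct = np.zeros(n)
    luminal = np.isin(subtype, ("luminal_A", "luminal_B", "luminal_HER2"))
    n_lum = int(luminal.sum())
    pattern = rng.choice(3, size=n_lum, p=[0.7, 0.2, 0.1])  # both, ER only, PgR only
    er_lum = np.where(pattern != 2, rng.integers(10, 96, size=n_lum), 0).astype(float)
    pgr_lum = np.where(pattern != 1, rng.integers(10, 96, size=n_lum), 0).astype(float)
    er_pct[luminal] = er_lum
    pgr_pct[luminal] = pgr_lum
    cols["ER_pct"] = er_pct
    cols["PgR_pct"] = pgr_pct

    ki67 = np.zeros(n)
    for st, (lo, hi) in {
        "luminal_A": (1, 14), "luminal_B": (14, 81), "luminal_HER2": (1, 91),
        "HER2_enriched": (15, 91), "triple_negative": (20, 91),
    }.items():
        mask = subtype == st
        ki67[mask] = rng.integers(lo, hi, size=int(mask.sum())).astype(float)
    cols["Ki67_pct"] = ki67

    her2_pos = np.isin(subtype, ("luminal_HER2", "HER2_enriched"))
    ihc = np.zeros(n, dtype=int)
    fish = np.full(n, np.nan)
    copies = np.full(n, np.nan)
    amp_by_ihc = rng.random(n) < 0.8
    ihc[her2_pos & amp_by_ihc] = 3
    eq = her2_pos & ~amp_by_ihc
    ihc[eq] = 2
    fish[eq] = np.round(rng.uniform(2.3, 8.0, size=int(eq.sum())), 2)
    copies[eq] = np.round(rng.uniform(6.5, 15.0, size=int(eq.sum())), 1)
    neg = ~her2_pos
    ihc_neg = rng.choice([0, 1, 2], size=int(neg.sum()), p=[0.5, 0.3, 0.2])
    ihc[neg] = ihc_neg
    neg_eq = neg.copy()
    neg_eq[neg] = ihc_neg == 2
    fish[neg_eq] = np.round(rng.uniform(0.8, 2.0, size=int(neg_eq.sum())), 2)
    copies[neg_eq] = np.round(rng.uniform(1.0, 4.0, size=int(neg_eq.sum())), 1)
    cols["HER2_ihc"] = ihc
    cols["HER2_fish_ratio"] = fish
    cols["HER2_copies"] = copies

    ck5_p = {"luminal_A": 0.03, "luminal_B": 0.05, "luminal_HER2": 0.05,
             "HER2_enriched": 0.15, "triple_negative": 0.45}
    ck5 = np.zeros(n, dtype=int)
    for st, p in ck5_p.items():
        mask = subtype == st
        ck5[mask] = (rng.random(int(mask.sum())) < p).astype(int)
    cols["CK5_any"] = ck5

    # true pathway-cluster memberships at the theoretical population medians
    med_a = population_irs_median(config, "IGF1Ra")
    med_2r = population_irs_median(config, "IGF2R")
    irs_a = irs_values[category[:, COPULA_MARKERS.index("IGF1Ra")]]
    irs_2r = irs_values[category[:, COPULA_MARKERS.index("IGF2R")]]
    lum_ab = np.isin(subtype, ("luminal_A", "luminal_B"))
    cluster_a2r = lum_ab & (irs_a >= med_a) & (irs_2r < med_2r)
    cluster_aeg = lum_ab & (irs_a >= med_a) & ~egfr_pos

    indicators = {
        "nodes_ge4": cov["nodes"] == "ge4",
        "surgery_BCS": cov["surgery"] == "BCS",
        "grade_III": cov["grade"] == "III",
        "size_gt2cm": cov["size"] == "gt2cm",
        "menopause_post": cov["menopause"] == "post",
        "taxane_yes": cov["taxane"] == "yes",
        "cluster_igf1ra_high_igf2r_low": cluster_a2r,
        "cluster_igf1ra_high_egfr_neg": cluster_aeg,
    }
    eta = np.zeros(n)
    for key, beta in config.log_hazard_coefficients.items():
        if key not in indicators:
            raise ValueError(f"unknown hazard coefficient key: {key}")
        if beta != 0.0:
            eta += beta * indicators[key].astype(float)

    # DFS is the earlier of the relapse and death processes; OS is the death
    # time itself, so both endpoints are exactly PH in eta and DFS <= OS.
    bh = config.baseline_hazard
    family, shape = bh["family"], bh.get("shape", 1.0)
    t_relapse = _sample_times(rng, bh["relapse"], eta, family, shape)
    t_death = _sample_times(rng, bh["death"], eta, family, shape)
    dfs_true = np.minimum(t_relapse, t_death)
    os_true = t_death

    horizon = config.censoring["horizon_months"]
    rate = config.censoring["dropout_rate"]
    if np.isinf(horizon):
        cens = np.full(n, np.inf)
    else:
        cens = np.full(n, horizon)
    if rate > 0 and not np.isinf(horizon):
        drop = rng.random(n) < rate
        cens[drop] = rng.uniform(0.1, horizon, size=int(drop.sum()))

    dfs_event = (dfs_true <= cens).astype(int)
    os_event = (os_true <= cens).astype(int)
    dfs_months = np.round(np.maximum(np.minimum(dfs_true, cens), 0.1), 2)
    os_months = np.round(np.maximum(np.minimum(os_true, cens), 0.1), 2)
    os_months = np.maximum(os_months, dfs_months)
    cols["dfs_months"] = dfs_months
    cols["dfs_event"] = dfs_event
    cols["os_months"] = os_months
    cols["os_event"] = os_event

    df = pd.DataFrame(cols)
    # missing-completely-at-random marker readings
    if config.missing_rate > 0:
        marker_cols = [
            "IGF1Ra_SI", "IGF1Ra_PP", "IGF1Rb_SI", "IGF1Rb_PP",
            "IGF2R_SI", "IGF2R_PP",
            "IGFBP2_weak_pct", "IGFBP2_moderate_pct", "IGFBP2_strong_pct",
            "EGFR_pct",
        ]
        groups = {
            "IGF1Ra": ["IGF1Ra_SI", "IGF1Ra_PP"],
            "IGF1Rb": ["IGF1Rb_SI", "IGF1Rb_PP"],
            "IGF2R": ["IGF2R_SI", "IGF2R_PP"],
            "IGFBP2": ["IGFBP2_weak_pct", "IGFBP2_moderate_pct", "IGFBP2_strong_pct"],
            "EGFR": ["EGFR_pct"],
        }
        del marker_cols
        for g, gcols in groups.items():
            miss = rng.random(n) < config.missing_rate
            df.loc[miss, gcols] = np.nan
    for c in ("IGF1Ra_SI", "IGF1Ra_PP", "IGF1Rb_SI", "IGF1Rb_PP",
              "IGF2R_SI", "IGF2R_PP", "HER2_ihc", "CK5_any",
              "dfs_event", "os_event"):
        df[c] = df[c].astype("Int64")

    truth = {
        "config": config,
        "subtype": pd.Series(subtype, name="subtype"),
        "latent_quantiles": pd.DataFrame(U, columns=list(COPULA_MARKERS)),
        "cluster_igf1ra_high_igf2r_low": pd.Series(cluster_a2r),
        "cluster_igf1ra_high_egfr_neg": pd.Series(cluster_aeg),
        "population_medians": {"IGF1Ra": med_a, "IGF2R": med_2r},
        "linear_predictor": pd.Series(eta),
    }
    return SyntheticCohort(cohort=Cohort(df), truth=truth)
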