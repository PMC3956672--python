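"""Combined aberrant-pathway biomarker variables and their survival analysis.

The two primary clusters single out hormone-receptor-positive tumors with a
presumptively hyperactive IGF1R axis:

* ``IGF1Ra_high_IGF2R_low`` — IGF1R-alpha IRS at/above its cut-off and
  IGF2R IRS below its cut-off (IGF2R acts as a non-signalling "buffer",
  so low IGF2R means less damping of IGF2 bioactivity);
* ``IGF1Ra_high_EGFR_neg`` — IGF1R-alpha high with EGFR-negative tumors
  (EGFR-mediated signalling absent, IGF1R presumed compensatory).

Each is compared with "the rest": all other patients within the same
subtype filter (luminal A + B by default; luminal-HER2 can be added as a
sensitivity analysis with an interaction test).  The four complementary
marker combinations serve as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from igfsurv import constants
from igfsurv.subtypes import SUBTYPES
from igfsurv.survival import CoxFit, cox_fit, four_year_rate, interaction_test, logrank_test

LUMINAL_AB = ("luminal_A", "luminal_B")


@dataclass(frozen=True)
class ClusterDefinition:
    """Membership predicate over two dichotomized/binary markers."""

    name: str
    marker_a: str          # score column, e.g. "IGF1Ra_IRS"
    a_high: bool           # member requires marker_a >= cutoff (True) or < (False)
    marker_b: str          # score column or "EGFR_status"
    b_high: bool
    subtype_filter: tuple[str, ...] = LUMINAL_AB


PRIMARY_CLUSTERS = (
    ClusterDefinition("IGF1Ra_high_IGF2R_low", "IGF1Ra_IRS", True, "IGF2R_IRS", False),
    ClusterDefinition("IGF1Ra_high_EGFR_neg", "IGF1Ra_IRS", True, "EGFR_status", False),
)

CONTROL_CLUSTERS = (
    ClusterDefinition("IGF1Ra_low_IGF2R_low", "IGF1Ra_IRS", False, "IGF2R_IRS", False),
    ClusterDefinition("IGF1Ra_high_IGF2R_high", "IGF1Ra_IRS", True, "IGF2R_IRS", True),
    ClusterDefinition("IGF1Ra_high_EGFR_high", "IGF1Ra_IRS", True, "EGFR_status", True),
    ClusterDefinition("IGF1Ra_low_EGFR_low", "IGF1Ra_IRS", False, "EGFR_status", False),
)


def _marker_high(scores: pd.DataFrame, marker: str, cutoffs: dict) -> pd.Series:
    """Boolean 'high' indicator (NA propagates) for a score or status column."""
    if marker.endswith("_status"):
        s = scores[marker]
        out = pd.Series(pd.NA, index=scores.index, dtype="boolean")
        out[s == "positive"] = True
        out[s == "negative"] = False
        return out
    cut = cutoffs[marker]
    vals = scores[marker].astype("Float64")
    out = pd.Series(pd.NA, index=scores.index, dtype="boolean")
    out[vals >= cut] = True
    out[vals < cut] = False
    return out


def assign_cluster(
    scores: pd.DataFrame,
    subtypes: pd.Series,
    definition: ClusterDefinition,
    cutoffs: dict,
) -> pd.Series:
    """Classify each patient as member / comparator / unassessable.

    Patients outside the definition's subtype filter, or with a missing
    constituent marker, are unassessable.
    """
    in_pop = subtypes.isin(definition.subtype_filter)
    a = _marker_high(scores, definition.marker_a, cutoffs)
    b = _marker_high(scores, definition.marker_b, cutoffs)
    member = (a == definition.a_high) & (b == definition.b_high)
    out = pd.Series("unassessable", index=scores.index, dtype=object)
    assessable = in_pop & a.notna() & b.notna()
    out[assessable] = np.where(member[assessable], "member", "comparator")
    return out


@dataclass
class ClusterAnalysisResult:
    definition: ClusterDefinition
    n_member: int
    n_comparator: int
    n_unassessable: int
    rates_4yr: dict = field(default_factory=dict)   # endpoint -> {member, comparator}
    logrank_p: dict = field(default_factory=dict)   # endpoint -> p
    univariate: dict = field(default_factory=dict)  # endpoint -> CoxFit
    multivariate: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict) # endpoint -> {hr, ci, p, p_interaction}
    gaps: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def coxrow(fit: CoxFit | None, cov: str = "member"):
            if fit is None or cov not in fit.summary.index:
                return None
            return {
                "hr": fit.hr(cov),
                "ci": list(fit.ci(cov)),
                "p": fit.p(cov),
                "converged": fit.converged,
                "n": fit.n,
                "n_events": fit.n_events,
            }

        return {
            "cluster": self.definition.name,
            "subtype_filter": list(self.definition.subtype_filter),
            "n_member": self.n_member,
            "n_comparator": self.n_comparator,
            "n_unassessable": self.n_unassessable,
            "rates_4yr": self.rates_4yr,
            "logrank_p": self.logrank_p,
            "univariate": {k: coxrow(v) for k, v in self.univariate.items()},
            "multivariate": {
                k: coxrow(v[0]) | {"retained": v[1]} if v[0] is not None else None
                for k, v in self.multivariate.items()
            },
            "sensitivity": self.sensitivity,
            "gaps": self.gaps,
        }


def run_cluster_analysis(
    cohort_df: pd.DataFrame,
    scores: pd.DataFrame,
    subtypes: pd.Series,
    definition: ClusterDefinition,
    cutoffs: dict,
    endpoints: dict[str, tuple],
    adjust: pd.DataFrame | None = None,
    adjust_blocks: dict[str, list[str]] | None = None,
    min_events: int = 10,
    sensitivity_subtype: str = "luminal_HER2",
) -> ClusterAnalysisResult:
    """Full survival comparison of cluster members versus the rest.

    ``endpoints`` maps endpoint name to ``(time, event)`` arrays aligned with
    the cohort.  4-year Kaplan-Meier rates use only assessable patients.
    When ``adjust`` (a clinical design matrix) is given, a multivariate model
    with backward elimination is fitted; the combined variable is always
    retained.  A sensitivity rerun adds ``sensitivity_subtype`` patients and
    reports the interaction test of cluster membership with the added group.
    """
    from igfsurv.survival import multivariate_model

    assign = assign_cluster(scores, subtypes, definition, cutoffs)
    member = assign == "member"
    comparator = assign == "comparator"
    assessable = member | comparator
    res = ClusterAnalysisResult(
        definition=definition,
        n_member=int(member.sum()),
        n_comparator=int(comparator.sum()),
        n_unassessable=int((assign == "unassessable").sum()),
    )
    idx = assessable.to_numpy()
    member_flag = member[assessable].to_numpy().astype(float)

    for name, (time, event) in endpoints.items():
        t = np.asarray(time, dtype=float)[idx]
        e = np.asarray(event, dtype=int)[idx]
        if e.sum() < min_events or member_flag.sum() == 0 or member_flag.sum() == len(member_flag):
            res.gaps.append(f"{name}: insufficient events or empty arm")
            continue
        res.rates_4yr[name] = {
            "member": four_year_rate(t[member_flag == 1], e[member_flag == 1]),
            "comparator": four_year_rate(t[member_flag == 0], e[member_flag == 0]),
        }
        res.logrank_p[name] = logrank_test(t, e, member_flag).p_value
        res.univariate[name] = cox_fit(t, e, pd.DataFrame({"member": member_flag}))
        if adjust is not None:
            X = adjust.loc[assessable].reset_index(drop=True).astype(float)
            X.insert(0, "member", member_flag)
            try:
                res.multivariate[name] = multivariate_model(
                    t, e, X, "member", blocks=adjust_blocks
                )
            except ValueError as exc:
                res.gaps.append(f"{name}: multivariate model failed ({exc})")

        # sensitivity: widen the population filter and test effect modification
        wider = definition.subtype_filter + (sensitivity_subtype,)
        wdef = ClusterDefinition(
            definition.name, definition.marker_a, definition.a_high,
            definition.marker_b, definition.b_high, subtype_filter=wider,
        )
        wassign = assign_cluster(scores, subtypes, wdef, cutoffs)
        wmask = (wassign != "unassessable").to_numpy()
        wm = (wassign[wmask] == "member").to_numpy().astype(float)
        added = subtypes[wmask].eq(sensitivity_subtype).to_numpy().astype(float)
        wt = np.asarray(time, dtype=float)[wmask]
        we = np.asarray(event, dtype=int)[wmask]
        try:
            wfit = cox_fit(wt, we, pd.DataFrame({"member": wm}))
            inter = interaction_test(wt, we, wm, added)
            res.sensitivity[name] = {
                "hr": wfit.hr("member"),
                "ci": list(wfit.ci("member")),
                "p": wfit.p("member"),
                "p_interaction": inter["p_interaction"],
            }
        except ValueError as exc:
            res.gaps.append(f"{name}: sensitivity analysis failed ({exc})")
    return res


def control_combinations(
    cohort_df: pd.DataFrame,
    scores: pd.DataFrame,
    subtypes: pd.Series,
    cutoffs: dict,
    endpoints: dict[str, tuple],
    **kwargs,
) -> dict[str, ClusterAnalysisResult]:
    """Run the four negative-control marker combinations."""
    return {
        d.name: run_cluster_analysis(
            cohort_df, scores, subtypes, d, cutoffs, endpoints, **kwargs
        )
        for d in CONTROL_CLUSTERS
    }
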