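"""Semiquantitative IHC scores and marker positivity rules.

Two scoring systems are implemented:

* the immunoreactive score ``IRS = SI x PP`` where SI is staining intensity
  (0 = none, 1 = weak, 2 = moderate, 3 = strong) and PP the percent-positive
  band (0 = 0%, 1 = under 10%, 2 = 10-49%, 3 = 50-100%); the attainable IRS
  values are the products {0, 1, 2, 3, 4, 6, 9};
* the H-score ``1*weak% + 2*moderate% + 3*strong%`` on intensity-band
  percentages, ranging 0-300.

Positivity rules for the classifier markers (ER, PgR, Ki67, HER2, EGFR,
CK5/6) follow the standard clinical conventions collected in
:mod:`igfsurv.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from igfsurv import constants
from igfsurv.cohort import Cohort

#: all attainable IRS values (products of SI, PP in 0..3)
IRS_VALUES = (0, 1, 2, 3, 4, 6, 9)


@dataclass(frozen=True)
class MarkerStatus:
    marker: str
    status: str | None  # "positive"/"negative", "high"/"low", or None if missing
    rule_applied: str


def bin_percent_positive(pct: float) -> int:
    """Map a percent of positive cells to the 0-3 percent-positive band.

    0 maps to band 0; the weak band covers percentages strictly between
    0 and 10; 10-49 maps to 2 and 50-100 to 3.
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percent positive out of range [0, 100]: {pct}")
    if pct == 0:
        return 0
    if pct < 10:
        return 1
    if pct < 50:
        return 2
    return 3


def compute_irs(si: int, pp_band: int) -> int:
    """Immunoreactive score: staining intensity times percent-positive band."""
    if si not in (0, 1, 2, 3):
        raise ValueError(f"staining intensity out of range 0..3: {si}")
    if pp_band not in (0, 1, 2, 3):
        raise ValueError(f"percent-positive band out of range 0..3: {pp_band}")
    return si * pp_band


def compute_hscore(weak: float, moderate: float, strong: float) -> float:
    """H-score: 1*weak% + 2*moderate% + 3*strong%, range 0-300.

    The three bands are percentages of cells; their sum may be below 100
    (unstained cells) but never above.
    """
    for name, v in (("weak", weak), ("moderate", moderate), ("strong", strong)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} percentage out of range [0, 100]: {v}")
    if weak + moderate + strong > 100 + 1e-9:
        raise ValueError(
            f"intensity-band percentages sum above 100: {weak + moderate + strong}"
        )
    return 1.0 * weak + 2.0 * moderate + 3.0 * strong


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x)


def marker_positivity(marker: str, **reading) -> MarkerStatus:
    """Apply the documented positivity rule for one classifier marker.

    Accepted markers and the raw fields they read:

    * ``ER`` / ``PgR``: ``pct`` — positive when at least 1% nuclear staining;
    * ``Ki67``: ``pct`` — high when >= 14%;
    * ``HER2``: ``ihc``, ``fish_ratio``, ``copies`` — positive when IHC 3+
      or FISH ratio > 2.2 or copy number > 6; all three missing gives a
      missing status, never negative;
    * ``EGFR``: ``pct`` — positive when >= 1% membrane staining;
    * ``CK5``: ``any_staining`` — positive on any specific staining.
    """
    if marker in ("ER", "PgR"):
        pct = reading.get("pct")
        if _isna(pct):
            return MarkerStatus(marker, None, "missing reading")
        status = "positive" if pct >= constants.ER_PGR_POSITIVE_PCT else "negative"
        return MarkerStatus(marker, status, f"nuclear staining >= {constants.ER_PGR_POSITIVE_PCT}%")
    if marker == "Ki67":
        pct = reading.get("pct")
        if _isna(pct):
            return MarkerStatus(marker, None, "missing reading")
        status = "high" if pct >= constants.KI67_HIGH_PCT else "low"
        return MarkerStatus(marker, status, f"proliferation index >= {constants.KI67_HIGH_PCT}%")
    if marker == "HER2":
        ihc = reading.get("ihc")
        ratio = reading.get("fish_ratio")
        copies = reading.get("copies")
        if _isna(ihc) and _isna(ratio) and _isna(copies):
            return MarkerStatus(marker, None, "all HER2 fields missing")
        positive = (
            (not _isna(ihc) and ihc == constants.HER2_IHC_POSITIVE)
            or (not _isna(ratio) and ratio > constants.HER2_FISH_RATIO)
            or (not _isna(copies) and copies > constants.HER2_COPY_NUMBER)
        )
        return MarkerStatus(
            marker,
            "positive" if positive else "negative",
            f"IHC 3+ or FISH ratio > {constants.HER2_FISH_RATIO} or copies > {constants.HER2_COPY_NUMBER}",
        )
    if marker == "EGFR":
        pct = reading.get("pct")
        if _isna(pct):
            return MarkerStatus(marker, None, "missing reading")
        status = "positive" if pct >= constants.EGFR_POSITIVE_PCT else "negative"
        return MarkerStatus(marker, status, f"membrane staining >= {constants.EGFR_POSITIVE_PCT}%")
    if marker == "CK5":
        flag = reading.get("any_staining")
        if _isna(flag):
            return MarkerStatus(marker, None, "missing reading")
        return MarkerStatus(marker, "positive" if flag else "negative", "any specific staining")
    raise ValueError(f"unknown marker: {marker}")


def dichotomize(scores, cutoff: float):
    """Split scores into 'high' (>= cutoff) and 'low'; missing propagates.

    Returns a pandas Series of the pandas nullable string dtype, aligned with
    the input.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) == 0:
        raise ValueError("cannot dichotomize an empty score vector")
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite: {cutoff}")
    out = pd.Series(pd.NA, index=s.index, dtype="string")
    out[s >= cutoff] = "high"
    out[s < cutoff] = "low"
    return out


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Derive per-patient scores and statuses from raw cohort readings.

    Returns a table indexed like the cohort with columns:
    ``IGF1Ra_IRS``, ``IGF1Rb_IRS``, ``IGF2R_IRS``, ``IGFBP2_H`` and the
    classifier statuses ``ER_status``, ``PgR_status``, ``Ki67_status``,
    ``HER2_status``, ``EGFR_status``, ``CK5_status``.  Patients with missing
    constituent readings get a missing score/status for that marker only.
    """
    df = cohort.df
    out = pd.DataFrame(index=df.index)
    out["patient_id"] = df["patient_id"]

    for marker in constants.IRS_MARKERS:
        si = df[f"{marker}_SI"]
        pp = df[f"{marker}_PP"]
        irs = (si.astype("Float64") * pp.astype("Float64"))
        out[f"{marker}_IRS"] = irs

    bands = df[["IGFBP2_weak_pct", "IGFBP2_moderate_pct", "IGFBP2_strong_pct"]]
    out["IGFBP2_H"] = (
        bands["IGFBP2_weak_pct"]
        + 2.0 * bands["IGFBP2_moderate_pct"]
        + 3.0 * bands["IGFBP2_strong_pct"]
    )

    out["ER_status"] = [
        marker_positivity("ER", pct=v).status for v in df["ER_pct"]
    ]
    out["PgR_status"] = [
        marker_positivity("PgR", pct=v).status for v in df["PgR_pct"]
    ]
    out["Ki67_status"] = [
        marker_positivity("Ki67", pct=v).status for v in df["Ki67_pct"]
    ]
    out["HER2_status"] = [
        marker_positivity("HER2", ihc=i, fish_ratio=r, copies=c).status
        for i, r, c in zip(df["HER2_ihc"], df["HER2_fish_ratio"], df["HER2_copies"])
    ]
    out["EGFR_status"] = [
        marker_positivity("EGFR", pct=v).status for v in df["EGFR_pct"]
    ]
    out["CK5_status"] = [
        marker_positivity("CK5", any_staining=v).status for v in df["CK5_any"]
    ]
    return out
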