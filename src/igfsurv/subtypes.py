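"""Five-class immunophenotype classifier for early breast cancer.

Hormone-receptor (HR) positivity means ER positive and/or PgR positive.
The classes are:

* ``luminal_A``      — HR positive, HER2 negative, Ki67 low (< 14%)
* ``luminal_B``      — HR positive, HER2 negative, Ki67 high (>= 14%)
* ``luminal_HER2``   — HR positive, HER2 positive (Ki67 not consulted)
* ``HER2_enriched``  — HR negative, HER2 positive
* ``triple_negative``— HR negative, HER2 negative (any EGFR/CK5 state)

Patients with both ER and PgR missing, or with an undetermined HER2 status,
or (when needed) missing Ki67 are ``unclassifiable`` — recorded explicitly,
never silently dropped.
"""

from __future__ import annotations

import pandas as pd

SUBTYPES = (
    "luminal_A",
    "luminal_B",
    "luminal_HER2",
    "HER2_enriched",
    "triple_negative",
)

HR_POSITIVE_SUBTYPES = ("luminal_A", "luminal_B", "luminal_HER2")

UNCLASSIFIABLE = "unclassifiable"


def classify(er, pgr, ki67, her2, egfr=None, ck5=None) -> str:
    """Assign one immunophenotype label from marker statuses.

    Statuses are the strings produced by :mod:`igfsurv.scoring`
    (``positive``/``negative`` for ER, PgR, HER2, EGFR, CK5; ``high``/``low``
    for Ki67), or ``None`` when missing.  EGFR and CK5 never change the
    label; they are accepted for interface symmetry.
    """
    er_known = er in ("positive", "negative")
    pgr_known = pgr in ("positive", "negative")
    if not er_known and not pgr_known:
        return UNCLASSIFIABLE
    hr_positive = (er == "positive") or (pgr == "positive")
    # HR negativity requires both receptors observed negative
    if not hr_positive and not (er == "negative" and pgr == "negative"):
        return UNCLASSIFIABLE
    if her2 not in ("positive", "negative"):
        return UNCLASSIFIABLE

    if hr_positive:
        if her2 == "positive":
            return "luminal_HER2"
        if ki67 == "low":
            return "luminal_A"
        if ki67 == "high":
            return "luminal_B"
        return UNCLASSIFIABLE
    if her2 == "positive":
        return "HER2_enriched"
    return "triple_negative"


def classify_cohort(scores: pd.DataFrame) -> pd.Series:
    """Classify every patient in a marker-status table from ``score_cohort``."""
    return pd.Series(
        [
            classify(er, pgr, ki67, her2, egfr, ck5)
            for er, pgr, ki67, her2, egfr, ck5 in zip(
                scores["ER_status"],
                scores["PgR_status"],
                scores["Ki67_status"],
                scores["HER2_status"],
                scores["EGFR_status"],
                scores["CK5_status"],
            )
        ],
        index=scores.index,
        name="subtype",
    )


def subtype_table(subtypes: pd.Series, by: pd.Series | None = None) -> pd.DataFrame:
    """Counts and percentages per subtype, optionally split by a covariate.

    Percentages are over classifiable patients and reported to one decimal.
    Returns an empty table (no crash) for an empty input.
    """
    classified = subtypes[subtypes.isin(SUBTYPES)]
    if by is None:
        counts = classified.value_counts().reindex(SUBTYPES, fill_value=0)
        total = int(counts.sum())
        pct = (100.0 * counts / total).round(1) if total else counts * 0.0
        return pd.DataFrame({"n": counts, "percent": pct})
    tab = pd.crosstab(classified, by.loc[classified.index]).reindex(
        SUBTYPES, fill_value=0
    )
    return tab
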