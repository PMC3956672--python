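"""Patient cohort container: schema, validation, and CSV round-trip I/O.

One row per patient. Clinicopathological covariates are coded as short
categorical strings, raw IHC readings as integers (staining intensity SI and
percent-positive band PP, both 0-3) or percentages, and follow-up as months
plus 0/1 event flags for disease-free survival (DFS) and overall survival
(OS).  Missing values are written as ``NA`` (empty cells are also accepted
on read).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A cohort table violates the documented schema."""


CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "menopause": ("pre", "post"),
    "nodes": ("0", "1-3", "ge4"),
    "size": ("le2cm", "gt2cm"),
    "grade": ("I-II", "III"),
    "histology": ("mixed", "ductal", "lobular", "other"),
    "surgery": ("MRM", "BCS"),
    "radiotherapy": ("yes", "no"),
    "hormonotherapy": ("yes", "no"),
    "taxane": ("yes", "no"),
}

SI_PP_COLUMNS = (
    "IGF1Ra_SI", "IGF1Ra_PP",
    "IGF1Rb_SI", "IGF1Rb_PP",
    "IGF2R_SI", "IGF2R_PP",
)

PCT_COLUMNS = (
    "IGFBP2_weak_pct", "IGFBP2_moderate_pct", "IGFBP2_strong_pct",
    "ER_pct", "PgR_pct", "Ki67_pct", "EGFR_pct",
)

COLUMNS: tuple[str, ...] = (
    "patient_id", "age_years",
    *CATEGORICAL_LEVELS,
    *SI_PP_COLUMNS,
    "IGFBP2_weak_pct", "IGFBP2_moderate_pct", "IGFBP2_strong_pct",
    "ER_pct", "PgR_pct", "Ki67_pct",
    "HER2_ihc", "HER2_fish_ratio", "HER2_copies",
    "EGFR_pct", "CK5_any",
    "dfs_months", "dfs_event", "os_months", "os_event",
)

_FLOAT_COLUMNS = (
    "age_years", *PCT_COLUMNS, "HER2_fish_ratio", "HER2_copies",
    "dfs_months", "os_months",
)
_INT_COLUMNS = (*SI_PP_COLUMNS, "HER2_ihc", "CK5_any", "dfs_event", "os_event")


@dataclass
class Cohort:
    """A validated patient table.

    Parameters
    ----------
    df : pandas.DataFrame
        Table with exactly the documented columns, one row per patient.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_cohort(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "Cohort") -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if col in _FLOAT_COLUMNS or col in _INT_COLUMNS:
                xa = pd.to_numeric(x).to_numpy(dtype=float)
                ya = pd.to_numeric(y).to_numpy(dtype=float)
                if not np.allclose(xa, ya, equal_nan=True, atol=1e-9):
                    return False
            else:
                if not x.fillna("NA").eq(y.fillna("NA")).all():
                    return False
        return True


def _err(row, col: str, msg: str) -> SchemaError:
    return SchemaError(f"row {row}, column {col!r}: {msg}")


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` on the first schema violation found."""
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")

    if df["patient_id"].isna().any():
        row = int(df.index[df["patient_id"].isna()][0])
        raise _err(row, "patient_id", "missing identifier")
    if df["patient_id"].duplicated().any():
        row = int(df.index[df["patient_id"].duplicated()][0])
        raise _err(row, "patient_id", "duplicate identifier")

    for col, levels in CATEGORICAL_LEVELS.items():
        vals = df[col].dropna()
        bad = ~vals.astype(str).isin(levels)
        if bad.any():
            row = int(vals.index[bad][0])
            raise _err(row, col, f"category {vals[bad].iloc[0]!r} not in {levels}")

    for col in SI_PP_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        provided = df[col].notna()
        unparsable = provided & vals.isna()
        if unparsable.any():
            row = int(df.index[unparsable][0])
            raise _err(row, col, "not an integer")
        out = vals.notna() & ~vals.isin([0, 1, 2, 3])
        if out.any():
            row = int(df.index[out][0])
            kind = "intensity" if col.endswith("_SI") else "percent-positive band"
            raise _err(row, col, f"{kind} out of range: {vals[out].iloc[0]} not in 0..3")

    for col in PCT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        out = vals.notna() & ((vals < 0) | (vals > 100))
        if out.any():
            row = int(df.index[out][0])
            raise _err(row, col, f"percentage out of range: {vals[out].iloc[0]}")

    bands = df[["IGFBP2_weak_pct", "IGFBP2_moderate_pct", "IGFBP2_strong_pct"]].apply(
        pd.to_numeric, errors="coerce"
    )
    total = bands.sum(axis=1, skipna=False)
    out = total.notna() & (total > 100 + 1e-9)
    if out.any():
        row = int(df.index[out][0])
        raise _err(row, "IGFBP2_weak_pct", "intensity-band percentages sum above 100")

    her2 = pd.to_numeric(df["HER2_ihc"], errors="coerce")
    out = her2.notna() & ~her2.isin([0, 1, 2, 3])
    if out.any():
        row = int(df.index[out][0])
        raise _err(row, "HER2_ihc", f"IHC score out of range: {her2[out].iloc[0]}")

    ck5 = pd.to_numeric(df["CK5_any"], errors="coerce")
    out = ck5.notna() & ~ck5.isin([0, 1])
    if out.any():
        row = int(df.index[out][0])
        raise _err(row, "CK5_any", "flag must be 0 or 1")

    for tcol, ecol in (("dfs_months", "dfs_event"), ("os_months", "os_event")):
        t = pd.to_numeric(df[tcol], errors="coerce")
        if t.isna().any():
            row = int(df.index[t.isna()][0])
            raise _err(row, tcol, "missing or non-numeric time")
        out = t <= 0
        if out.any():
            row = int(df.index[out][0])
            raise _err(row, tcol, f"non-positive time: {t[out].iloc[0]}")
        e = pd.to_numeric(df[ecol], errors="coerce")
        out = e.isna() | ~e.isin([0, 1])
        if out.any():
            row = int(df.index[out][0])
            raise _err(row, ecol, "event flag must be 0 or 1")

    dfs = pd.to_numeric(df["dfs_months"])
    os_ = pd.to_numeric(df["os_months"])
    out = dfs > os_ + 1e-9
    if out.any():
        row = int(df.index[out][0])
        raise _err(row, "dfs_months", "DFS time exceeds OS time")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; missing values are written as ``NA``."""
    cohort.df.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, **{c: str for c in CATEGORICAL_LEVELS}},
        na_values=["NA", ""],
        keep_default_na=False,
    )
    for col in _FLOAT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return Cohort(df)


def cohort_to_csv_bytes(cohort: Cohort) -> bytes:
    """Serialize to the canonical CSV byte representation (for determinism checks)."""
    buf = io.StringIO()
    cohort.df.to_csv(buf, index=False, na_rep="NA", float_format="%.10g")
    return buf.getvalue().encode()
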