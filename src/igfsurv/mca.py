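"""Multiple correspondence analysis (MCA) of dichotomized biomarkers.

Indicator-matrix MCA: each categorical variable is expanded to dummy
columns, the resulting n x J matrix is analyzed as a correspondence table
(chi-square metric, row-profile centering, singular value decomposition).
Principal inertias are the squared singular values; with complete data the
total inertia equals ``J/Q - 1`` where Q is the number of variables and J
the total number of observed categories.

No Benzecri/Greenacre inertia correction is applied by default (raw
per-dimension inertia percentages are reported); the Benzecri adjustment is
available behind a flag for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MCAResult:
    n_rows: int
    n_dropped: int
    Q: int                       # number of variables
    J: int                       # total observed categories
    eigenvalues: np.ndarray      # principal inertias, nonincreasing
    inertia_pct: np.ndarray      # percent of total inertia per dimension
    total_inertia: float
    coordinates: pd.DataFrame = field(repr=False)  # categories x dimensions
    column_masses: pd.Series = field(repr=False)
    benzecri: bool = False

    def cumulative_inertia_pct(self) -> np.ndarray:
        return np.cumsum(self.inertia_pct)


def _indicator(table: pd.DataFrame) -> pd.DataFrame:
    parts = []
    for col in table.columns:
        d = pd.get_dummies(table[col].astype(str), prefix=col, prefix_sep="=")
        parts.append(d)
    return pd.concat(parts, axis=1).astype(float)


def mca_fit(table: pd.DataFrame, benzecri: bool = False) -> MCAResult:
    """Fit indicator-matrix MCA to a table of categorical variables.

    Rows with any missing value are excluded (complete-case analysis; the
    dropped count is reported).  Categories observed zero times are dropped
    with a warning.  Coordinates are category principal coordinates.
    """
    if table.shape[1] < 2:
        raise ValueError("MCA requires at least two variables")
    complete = table.dropna()
    n_dropped = len(table) - len(complete)
    if len(complete) == 0:
        raise ValueError("no complete cases for MCA")
    for col in complete.columns:
        if complete[col].nunique() < 2:
            raise ValueError(f"variable {col!r} has fewer than two observed categories")

    Z = _indicator(complete)
    zero = Z.columns[(Z.sum(axis=0) == 0)]
    if len(zero):
        warnings.warn(f"dropping never-observed categories: {list(zero)}")
        Z = Z.drop(columns=list(zero))
    n, J = Z.shape
    Q = complete.shape[1]

    N = Z.to_numpy().sum()
    P = Z.to_numpy() / N
    r = P.sum(axis=1)            # = 1/n for complete data
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    eig = sv**2
    # keep the J - Q structural dimensions (trailing ones are numerically zero)
    k = J - Q
    eig = eig[:k]
    sv = sv[:k]
    Vt = Vt[:k]
    total = float(eig.sum())

    # principal coordinates of the categories
    G = (Vt.T / np.sqrt(c)[:, None]) * sv[None, :]
    coords = pd.DataFrame(
        G, index=Z.columns, columns=[f"dim{i + 1}" for i in range(k)]
    )

    if benzecri:
        thr = 1.0 / Q
        adj = np.where(eig > thr, (Q / (Q - 1.0) * (eig - thr)) ** 2, 0.0)
        pct = 100.0 * adj / adj.sum() if adj.sum() > 0 else np.zeros_like(adj)
    else:
        pct = 100.0 * eig / total

    return MCAResult(
        n_rows=n,
        n_dropped=n_dropped,
        Q=Q,
        J=J,
        eigenvalues=eig,
        inertia_pct=pct,
        total_inertia=total,
        coordinates=coords,
        column_masses=pd.Series(c, index=Z.columns),
        benzecri=benzecri,
    )


@dataclass
class AssociationSummary:
    marker_a: str
    marker_b: str
    category_a: str
    category_b: str
    cosine: float
    opposite_side: dict  # dimension -> bool (True when signs differ)
    conclusive: bool
    direction: str       # "inverse", "direct" or "inconclusive"


def inverse_association_check(
    result: MCAResult,
    marker_pair: tuple[str, str],
    categories: tuple[str, str] = ("high", "high"),
    dims: list[str] | None = None,
    min_cosine: float = 0.3,
) -> AssociationSummary:
    """Signed co-location of two markers' chosen categories in MCA space.

    Computes the cosine between the two category coordinate vectors over the
    requested dimensions (all by default).  A strongly negative cosine means
    the categories load on opposite sides — an inverse association; small
    magnitudes are flagged inconclusive.
    """
    a, b = marker_pair
    ca = f"{a}={categories[0]}"
    cb = f"{b}={categories[1]}"
    for cat in (ca, cb):
        if cat not in result.coordinates.index:
            raise ValueError(f"category {cat!r} not in fitted MCA table")
    dims = dims or list(result.coordinates.columns)
    va = result.coordinates.loc[ca, dims].to_numpy(dtype=float)
    vb = result.coordinates.loc[cb, dims].to_numpy(dtype=float)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    cosine = float(va @ vb / denom) if denom > 0 else 0.0
    opposite = {d: bool(np.sign(va[i]) != np.sign(vb[i])) for i, d in enumerate(dims)}
    conclusive = abs(cosine) >= min_cosine
    direction = (
        "inconclusive" if not conclusive else ("inverse" if cosine < 0 else "direct")
    )
    return AssociationSummary(a, b, ca, cb, cosine, opposite, conclusive, direction)
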