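import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from igfsurv.cohort import COLUMNS, Cohort
from igfsurv.synthetic import SimulationConfig, generate_cohort


def make_patient(pid="P1", **overrides):
    """One schema-complete patient row with sensible defaults."""
    row = {
        "patient_id": pid,
        "age_years": 55.0,
        "menopause": "post",
        "nodes": "1-3",
        "size": "gt2cm",
        "grade": "I-II",
        "histology": "ductal",
        "surgery": "MRM",
        "radiotherapy": "yes",
        "hormonotherapy": "yes",
        "taxane": "yes",
        "IGF1Ra_SI": 2, "IGF1Ra_PP": 3,
        "IGF1Rb_SI": 0, "IGF1Rb_PP": 0,
        "IGF2R_SI": 1, "IGF2R_PP": 1,
        "IGFBP2_weak_pct": 20.0, "IGFBP2_moderate_pct": 30.0, "IGFBP2_strong_pct": 10.0,
        "ER_pct": 80.0, "PgR_pct": 40.0, "Ki67_pct": 10.0,
        "HER2_ihc": 1, "HER2_fish_ratio": np.nan, "HER2_copies": np.nan,
        "EGFR_pct": 0.0, "CK5_any": 0,
        "dfs_months": 60.0, "dfs_event": 0, "os_months": 60.0, "os_event": 0,
    }
    row.update(overrides)
    return row


def make_cohort(rows) -> Cohort:
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return Cohort(df)


@pytest.fixture
def tiny_cohort() -> Cohort:
    return make_cohort(
        [
            make_patient("P1"),
            make_patient("P2", ER_pct=0.0, PgR_pct=0.0, HER2_ihc=3,
                         dfs_months=24.0, dfs_event=1, os_months=40.0, os_event=1),
            make_patient("P3", Ki67_pct=30.0, IGF1Ra_SI=np.nan, IGF1Ra_PP=np.nan),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized synthetic cohort shared across read-only tests."""
    return generate_cohort(SimulationConfig(n_patients=1021, seed=20260101))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort in which no marker or covariate affects the hazard."""
    cfg = SimulationConfig(
        n_patients=1000,
        seed=20260102,
        log_hazard_coefficients={},
    )
    return generate_cohort(cfg)
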