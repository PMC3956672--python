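"""Clinically defined thresholds used throughout the pipeline.

All thresholds live here so a run configuration can override any of them in
one place; every analysis module imports from this file rather than
hard-coding values.
"""

# ER / PgR: positive nuclear staining in at least this percent of cancer cells
ER_PGR_POSITIVE_PCT = 1.0

# Ki67 proliferation index: high when >= this percent (Cheang et al. convention)
KI67_HIGH_PCT = 14.0

# HER2 positivity: IHC 3+, or FISH amplification by ratio or copy number
HER2_IHC_POSITIVE = 3
HER2_FISH_RATIO = 2.2   # positive when ratio strictly greater
HER2_COPY_NUMBER = 6.0  # positive when copies strictly greater

# EGFR: any membrane staining above background in >= this percent of cells
EGFR_POSITIVE_PCT = 1.0

# Kaplan-Meier landmark used for "4-year" survival rates (months)
FOUR_YEAR_MONTHS = 48.0

# Significance levels: univariate tests and multivariate retention
ALPHA_UNIVARIATE = 0.05
ALPHA_STAY_MULTIVARIATE = 0.15

# Markers quantified with the immunoreactive score (SI x PP)
IRS_MARKERS = ("IGF1Ra", "IGF1Rb", "IGF2R")

# Marker quantified with the H-score (weighted intensity-band percentages)
HSCORE_MARKERS = ("IGFBP2",)
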