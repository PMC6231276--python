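"""Default calibration constants for the synthetic claims generator.

The defaults emulate a 2015 Colombian subsidized-regime insurance cohort of
20,410 asthma patients: the four-category severity mixture, per-severity
demographic margins, comorbidity prevalences, per-(severity x component)
annual cost cells in 2015 International Dollars (I$), utilization
probabilities, and the multiplicative covariate/severity effect structure of
a gamma log-link cost model fitted to that cohort.  All constants are plain
data; the arithmetic that turns them into per-event gamma parameters lives
in :mod:`asthmacost.simulate`.

Severity order everywhere: (mild intermittent, mild persistent, moderate
persistent, severe persistent).
"""

from __future__ import annotations

import numpy as np

#: COP per 2015 International Dollar (World Bank PPP conversion factor).
PPP_RATE_COP_PER_IUSD = 1203.9

#: Reference cohort stratum sizes, mild intermittent .. severe persistent.
CATEGORY_SIZES = (14191, 3680, 1408, 1131)

SEVERITY_LABELS = (
    "mild_intermittent",
    "mild_persistent",
    "moderate_persistent",
    "severe_persistent",
)

#: Exact severity mixture implied by the stratum sizes (sums to 1).
SEVERITY_MIXTURE = tuple(n / sum(CATEGORY_SIZES) for n in CATEGORY_SIZES)

SERVICE_TYPES = (
    "ed_visit",
    "hospitalization",
    "specialized_physician_visit",
    "general_physician_visit",
    "other_ambulatory",
)

MEDICATION_CLASSES = ("ICS", "ICS_LABA", "LABA", "LM", "theophylline", "OCS", "SABA")

# ---------------------------------------------------------------------------
# Demographic margins per severity stratum.
# ---------------------------------------------------------------------------

AGE_BANDS = ((0, 4), (5, 9), (10, 14), (15, 19), (20, 44), (45, 59), (60, 90))

#: P(age band | severity); columns follow SEVERITY_LABELS, rows AGE_BANDS.
AGE_BAND_PROBS = {
    (0, 4): (0.346, 0.387, 0.385, 0.437),
    (5, 9): (0.160, 0.131, 0.126, 0.106),
    (10, 14): (0.082, 0.081, 0.066, 0.046),
    (15, 19): (0.043, 0.036, 0.022, 0.020),
    (20, 44): (0.154, 0.142, 0.100, 0.092),
    (45, 59): (0.094, 0.092, 0.108, 0.134),
    (60, 90): (0.117, 0.128, 0.190, 0.163),
}

FEMALE_PROB = (0.541, 0.529, 0.542, 0.487)
URBAN_PROB = (0.785, 0.842, 0.826, 0.835)

#: P(SISBEN level | severity); level 1 = most deprived.
SISBEN_PROBS = {
    "1": (0.865, 0.868, 0.846, 0.863),
    "2": (0.095, 0.086, 0.118, 0.094),
    "3": (0.005, 0.003, 0.005, 0.005),
    "other": (0.034, 0.041, 0.029, 0.036),
}

#: P(comorbidity flag | severity), count-derived.
COMORBIDITY_PREVALENCE = {
    "rhinitis": (0.050, 0.067, 0.094, 0.106),
    "acute_bronchitis": (0.013, 0.020, 0.037, 0.032),
    "copd": (0.076, 0.129, 0.242, 0.289),
    "atopic_eczema": (0.029, 0.038, 0.049, 0.044),
    "emphysema": (0.0020, 0.0046, 0.0099, 0.0097),
}

#: Fraction of patients whose recorded sex is missing in the claims extract.
MISSING_SEX_FRACTION = 179 / 20410

# ---------------------------------------------------------------------------
# Utilization probabilities per severity (probability of >=1 event/fill).
# SABA, OCS and exacerbation counts are not listed here: they are drawn
# jointly from the severity rule region so the classifier round-trips.
# ---------------------------------------------------------------------------

UTILIZATION_PROBS = {
    "specialized_physician_visit": (0.249, 0.287, 0.410, 0.521),
    "general_physician_visit": (0.595, 0.478, 0.536, 0.641),
    "other_ambulatory": (0.071, 0.080, 0.113, 0.165),
    "ICS": (0.125, 0.383, 0.583, 0.736),
    "ICS_LABA": (0.002, 0.024, 0.121, 0.173),
    "LABA": (0.0013, 0.017, 0.027, 0.059),
    "LM": (0.0, 0.060, 0.109, 0.252),
    "theophylline": (0.0025, 0.0168, 0.0447, 0.0698),
}

#: Mean extra events beyond the first for a user (count = 1 + Poisson(lambda)).
EXTRA_EVENTS_POISSON_MEAN = 0.5

#: Fraction of exacerbation events billed as ED visits (rest hospitalizations),
#: per severity; mild intermittent has structurally zero exacerbations.
ED_FRACTION_OF_EXACERBATIONS = (0.0, 0.483, 0.337, 0.129)

# ---------------------------------------------------------------------------
# Annual per-patient cost cells in I$, (mean, SD) per severity stratum,
# all-members basis.  Service residuals (1-3 I$ of rounding between the
# printed service rows and the any-service row) are folded into
# other_ambulatory; the unprinted theophylline row carries the medication
# residual that closes the any-medication margin (it stands for theophylline
# plus unlisted asthma medications).  Component means therefore sum exactly
# to the per-category total means (67, 482, 1061, 2235).
# ---------------------------------------------------------------------------

COST_CELLS = {
    "ed_visit": ((0.0, 0.0), (21.0, 57.0), (26.0, 78.0), (20.0, 87.0)),
    "hospitalization": ((0.0, 0.0), (239.0, 1492.0), (368.0, 1838.0), (662.0, 2027.0)),
    "specialized_physician_visit": ((15.0, 35.0), (23.0, 52.0), (38.0, 66.0), (58.0, 91.0)),
    "general_physician_visit": ((30.0, 39.0), (41.0, 59.0), (54.0, 77.0), (100.0, 158.0)),
    "other_ambulatory": ((6.0, 61.0), (11.0, 85.0), (12.0, 49.0), (25.0, 99.0)),
    "ICS": ((5.0, 52.0), (28.0, 117.0), (84.0, 269.0), (101.0, 306.0)),
    "ICS_LABA": ((0.7, 19.0), (12.0, 115.0), (147.0, 513.0), (208.0, 606.0)),
    "LABA": ((0.2, 2.0), (0.7, 14.0), (0.8, 11.0), (5.0, 62.0)),
    "LM": ((0.0, 0.0), (10.0, 61.0), (37.0, 143.0), (137.0, 296.0)),
    "theophylline": ((7.1, 14.2), (43.3, 86.6), (148.2, 296.4), (615.0, 1230.0)),
    "OCS": ((0.0, 0.0), (15.0, 36.0), (48.0, 100.0), (138.0, 249.0)),
    "SABA": ((3.0, 27.0), (38.0, 114.0), (98.0, 231.0), (166.0, 375.0)),
}

#: Reference unadjusted mean annual total cost per stratum, I$ (= column sums
#: of COST_CELLS by construction).
CATEGORY_TOTAL_MEANS = tuple(
    round(sum(COST_CELLS[c][s][0] for c in COST_CELLS), 6) for s in range(4)
)

#: Reference unadjusted SD of annual total cost per stratum, I$.
CATEGORY_TOTAL_SDS = (134.0, 1506.0, 1983.0, 3426.0)

# ---------------------------------------------------------------------------
# Multiplicative effect structure of the gamma log-link cost model
# (cost ratios; reference categories in parentheses).
# ---------------------------------------------------------------------------

EFFECT_RATIOS = {
    "age": 1.00,            # per year of age
    "female": 0.97,         # vs male
    "sisben_level1": 0.88,  # vs SISBEN levels 2-3/other
    "rhinitis": 1.76,
    "acute_bronchitis": 1.34,
    "atopic_eczema": 1.12,
    "copd": 1.65,
    "emphysema": 1.29,
    "urban": 1.15,          # vs rural
}

#: Severity cost ratios vs mild intermittent.
SEVERITY_RATIOS = (1.0, 6.63, 13.59, 28.84)


def _normalized(p):
    a = np.asarray(p, dtype=float)
    return a / a.sum()


def age_band_matrix() -> np.ndarray:
    """(n_bands, 4) matrix of P(band | severity), columns normalised."""
    m = np.array([AGE_BAND_PROBS[b] for b in AGE_BANDS], dtype=float)
    return m / m.sum(axis=0, keepdims=True)


def sisben_matrix() -> tuple[list[str], np.ndarray]:
    levels = list(SISBEN_PROBS)
    m = np.array([SISBEN_PROBS[k] for k in levels], dtype=float)
    return levels, m / m.sum(axis=0, keepdims=True)
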