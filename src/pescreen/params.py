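"""Shipped default parameters of the screening model and cohort generator.

The defaults encode the published summary statistics of a Shenzhen
first-trimester screening cohort of 3,270 singleton pregnancies (median
gestational age at screening 89 days): group-wise MoM medians and IQRs for
MAP, PLGF and PAPP-A; maternal characteristic distributions; and the outcome
flow (8 early PE, 35 late PE — 15 of the 43 PE pregnancies also SGA — and 84
SGA without PE).

The vendor software's internal parameters (median equations, prior LR table,
marker Gaussians) are proprietary and unpublished, so the median-model slopes
and the prior LR table shipped here are explicitly *placeholder* values set
to screening-literature conventions and calibrated only loosely (cohort mean
prior near the study incidence).  Every value is refittable or overridable
through configuration.
"""

from __future__ import annotations

import numpy as np

from .mom import MarkerMedianModel, MedianModel
from .risk import PriorModel

__all__ = [
    "GROUP_MOM_STATS",
    "UNAFFECTED_CONCENTRATION_MEDIANS",
    "MATERNAL_STATS",
    "OUTCOME_COUNTS",
    "REFERENCE_GA_DAYS",
    "REFERENCE_WEIGHT_KG",
    "default_median_model",
    "default_prior_model",
]

#: Median gestational age at screening (days) at which the concentration
#: medians below were observed.
REFERENCE_GA_DAYS = 89
#: Cohort median maternal weight (kg), the weight-adjustment centering point.
REFERENCE_WEIGHT_KG = 53.0

#: Group-wise MoM summary statistics: marker -> (median, q1, q3).
GROUP_MOM_STATS: dict[str, dict[str, tuple[float, float, float]]] = {
    "unaffected": {
        "plgf": (1.11, 0.79, 1.47),
        "pappa": (0.93, 0.67, 1.29),
        "map": (0.97, 0.90, 1.04),
    },
    "early_pe": {
        "plgf": (0.72, 0.49, 0.90),
        "pappa": (0.49, 0.28, 1.15),
        "map": (1.13, 1.10, 1.18),
    },
    "late_pe": {
        "plgf": (0.59, 0.41, 0.87),
        "pappa": (0.83, 0.50, 1.17),
        "map": (1.04, 0.99, 1.12),
    },
    "sga_no_pe": {
        "plgf": (0.92, 0.63, 1.28),
        "pappa": (0.87, 0.52, 1.20),
        "map": (0.98, 0.90, 1.07),
    },
}

#: Concentration medians observed in the unaffected group (at the MoM medians
#: above and gestational age REFERENCE_GA_DAYS): PLGF pg/mL, PAPP-A mU/L,
#: MAP mmHg.
UNAFFECTED_CONCENTRATION_MEDIANS = {"plgf": 43.61, "pappa": 4074.56, "map": 78.83}

#: Outcome flow of the study cohort (fixed-count generator mode).
OUTCOME_COUNTS = {
    "early_pe_sga": 5,
    "early_pe_aga": 3,
    "late_pe_sga": 10,
    "late_pe_aga": 25,
    "sga_no_pe": 84,
    "unaffected": 3143,
}

#: Maternal characteristic summaries: (median, q1, q3) for continuous fields,
#: rates for binaries; split by PE status as published.
MATERNAL_STATS = {
    "non_pe": {
        "maternal_age": (30.0, 28.0, 34.0),
        "weight_kg": (53.00, 48.80, 58.60),
        "height_cm": (160.00, 156.00, 163.00),
        "crl_mm": (63.0, 59.0, 68.0),
        "ga_screening_days": (89.0, 86.0, 91.0),
        "ga_delivery_wk": (39.0, 38.0, 40.0),
        "birth_weight_g": (3270.0, 3010.0, 3550.0),
        "smoking_rate": 2 / 3227,
        "chronic_htn_rate": 19 / 3227,
        "ivf_rate": 33 / 3227,
        "nulliparous_rate": 0.55,
        "prior_pe_rate_parous": 0.01,
    },
    "pe": {
        "maternal_age": (30.0, 28.0, 34.0),
        "weight_kg": (56.00, 51.50, 65.00),
        "height_cm": (157.75, 154.75, 162.25),
        "crl_mm": (62.0, 56.0, 67.0),
        "ga_screening_days": (88.0, 85.0, 91.0),
        "ga_delivery_wk": (36.0, 35.0, 39.0),
        "birth_weight_g": (2460.0, 1930.0, 3030.0),
        "smoking_rate": 0.0,
        "chronic_htn_rate": 8 / 43,
        "ivf_rate": 0.0,
        "nulliparous_rate": 0.70,
        "prior_pe_rate_parous": 0.15,
    },
}

# Placeholder log10(level)-per-GA-day slopes (screening-literature shape:
# PAPP-A rises steeply across the window, PLGF moderately, MAP is flat).
_MEDIAN_SLOPES = {"plgf": 0.005, "pappa": 0.012, "map": 0.0}
# Placeholder log10(MoM)-per-kg weight-adjustment slopes for serum markers.
_WEIGHT_SLOPES = {"plgf": -0.004, "pappa": -0.006}
# Placeholder multiplicative smoking factors (smoking raises PLGF, lowers
# PAPP-A in the screening literature; near-irrelevant at this cohort's 0.06%
# smoking rate).
_SMOKING_FACTORS = {"plgf": 1.2, "pappa": 0.85}


def default_median_model() -> MedianModel:
    """Shipped (vendor-like) median model, anchored to the unaffected-group
    concentration medians at gestational day 89.

    The intercepts solve ``concentration_median = MoM_median * 10**(a + b*89)``
    so that the unaffected population lands on its published MoM medians.
    """
    markers = {}
    for marker, slope in _MEDIAN_SLOPES.items():
        mom_med, _, _ = GROUP_MOM_STATS["unaffected"][marker]
        con_med = UNAFFECTED_CONCENTRATION_MEDIANS[marker]
        intercept = float(np.log10(con_med / mom_med) - slope * REFERENCE_GA_DAYS)
        markers[marker] = MarkerMedianModel(
            intercept=intercept,
            slope=slope,
            weight_slope=_WEIGHT_SLOPES.get(marker, 0.0),
            ethnicity_factors={"chinese": 1.0, "other": 1.0},
            smoking_factor=_SMOKING_FACTORS.get(marker, 1.0),
        )
    return MedianModel(markers=markers, reference_weight=REFERENCE_WEIGHT_KG)


def default_prior_model() -> PriorModel:
    """Placeholder prior model over the five maternal risk factors.

    Baseline risks and LRs are set so the default cohort's mean prior lands
    near the study incidence (0.24% early, 1.07% late, 1.31% overall); they
    are refittable configuration, not the vendor's parameters.
    """
    lr_common = {
        "ethnicity": {"chinese": 1.0, "other": 1.0},
    }
    return PriorModel(
        baseline={"early": 0.0012, "late": 0.007},
        lr_tables={
            "early": {
                **lr_common,
                "bmi": {"<25": 1.0, "25-30": 1.8, ">=30": 3.0},
                "parity": {"nulliparous": 2.0, "parous": 1.0},
                "prior_pe": {"true": 8.0, "false": 1.0},
                "chronic_htn": {"true": 10.0, "false": 1.0},
            },
            "late": {
                **lr_common,
                "bmi": {"<25": 1.0, "25-30": 1.6, ">=30": 2.5},
                "parity": {"nulliparous": 1.5, "parous": 1.0},
                "prior_pe": {"true": 5.0, "false": 1.0},
                "chronic_htn": {"true": 5.0, "false": 1.0},
            },
        },
    )
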