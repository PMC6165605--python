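"""Bundled worked example: thermal pretreatment of hotel food waste.

Measured inputs from a published batch-digestion study of hotel food waste
pretreated in hot water at 60/80/100 degC for 10 or 20 minutes: the
alternatives-by-criteria decision matrix for the multicriteria ranking, the
45-day and 12-day cumulative biogas yields, the feedstock ultimate
analysis, and the bottle geometry of the assay.  These serve the same role
as the example datasets shipped with statistics packages: a small, fully
printed input on which every pipeline stage has a known answer.
"""

from __future__ import annotations

import numpy as np

from .energetics import UltimateAnalysis
from .entropy_vikor import DecisionMatrix
from .pretreatment import PretreatmentCondition

__all__ = [
    "MEASUREMENT_DAYS",
    "HEADSPACE_VOLUME_L",
    "INCUBATION_TEMPERATURE_K",
    "SUBSTRATE_VS_MASS_G",
    "CONDITION_LABELS",
    "PRETREATMENT_CONDITIONS",
    "BIOGAS_YIELD_45D",
    "BIOGAS_YIELD_12D",
    "GOMPERTZ_LAG_DAYS",
    "MEASURED_CH4_FRACTION",
    "FOOD_WASTE_ULTIMATE",
    "decision_matrix",
]

#: Days on which headspace pressure was read (bottle vented after each).
MEASUREMENT_DAYS = (1, 2, 3, 4, 6, 9, 12, 15, 18, 22, 27, 32, 45)

# Bottle geometry: 610 mL serum bottles with 400 mL working volume at
# 37 degC; substrate loaded to 1.5 g VS/L of working volume.
HEADSPACE_VOLUME_L = 0.21
INCUBATION_TEMPERATURE_K = 310.15
SUBSTRATE_VS_MASS_G = 0.6

CONDITION_LABELS = (
    "Untreated",
    "60C, 10 min",
    "60C, 20 min",
    "80C, 10 min",
    "80C, 20 min",
    "100C, 10 min",
    "100C, 20 min",
)

PRETREATMENT_CONDITIONS = (
    PretreatmentCondition("Untreated", 0.0, 0.0),
    PretreatmentCondition("60C, 10 min", 60.0, 10.0),
    PretreatmentCondition("60C, 20 min", 60.0, 20.0),
    PretreatmentCondition("80C, 10 min", 80.0, 10.0),
    PretreatmentCondition("80C, 20 min", 80.0, 20.0),
    PretreatmentCondition("100C, 10 min", 100.0, 10.0),
    PretreatmentCondition("100C, 20 min", 100.0, 20.0),
)

#: 45-day cumulative specific biogas yield per condition, mL/g VS.
BIOGAS_YIELD_45D = dict(zip(CONDITION_LABELS, (555, 575, 645, 653, 692, 783, 728)))

#: Cumulative yield at day 12 (the steep part of the curve), mL/g VS.
BIOGAS_YIELD_12D = dict(zip(CONDITION_LABELS, (410, 398, 458, 501, 556, 652, 607)))

#: Reported modified-Gompertz lag phases, days.
GOMPERTZ_LAG_DAYS = dict(
    zip(CONDITION_LABELS, (0.5, 0.06, 0.05, 0.03, 0.02, 0.01, 0.0))
)

#: Measured average methane content of the produced biogas.
MEASURED_CH4_FRACTION = 0.62

#: Ultimate analysis of the food-waste feedstock, mass % of dry matter.
FOOD_WASTE_ULTIMATE = UltimateAnalysis(
    carbon=49.5, hydrogen=9.9, nitrogen=2.7, oxygen=36.1, sulphur=0.3
)


def decision_matrix() -> DecisionMatrix:
    """Six pretreated alternatives scored on five post-pretreatment criteria.

    Criteria: pH, VS reduction (%), soluble COD (g/L), soluble protein
    (g/L) and 45-day biogas yield (mL/g VS).  All five are treated as
    benefit criteria in the study's ranking.
    """
    return DecisionMatrix(
        alternative_labels=(
            "60C, 10 min",
            "60C, 20 min",
            "80C, 10 min",
            "80C, 20 min",
            "100C, 10 min",
            "100C, 20 min",
        ),
        criterion_labels=("pH", "VS reduction (%)", "sCOD (g/L)", "Soluble protein (g/L)", "Biogas yield (mL/g VS)"),
        values=np.array(
            [
                [5.69, 17.09, 83.85, 21.6, 575.66],
                [5.29, 16.87, 88.62, 21.8, 645.73],
                [5.66, 16.66, 91.36, 22.6, 653.24],
                [5.19, 16.49, 92.45, 22.9, 692.68],
                [5.58, 16.26, 101.56, 23.3, 783.23],
                [4.96, 16.09, 100.12, 23.7, 728.48],
            ]
        ),
        orientations=("benefit",) * 5,
    )
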