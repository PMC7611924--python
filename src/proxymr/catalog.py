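"""The first-degree-relative outcome catalogue.

Twelve self-reported diseases plus parental vital status and age at death,
crossed with relative type (father / mother / sibling) under an
applicability mask (no breast cancer in fathers, no prostate cancer in
mothers, no vital information for siblings) -- 38 outcome slots in total.

``FAMILY_HISTORY_COUNTS`` holds published descriptive case / denominator
counts of these outcomes as self-reported at enrolment by UK Biobank
participants; they calibrate default simulation prevalences and anchor the
descriptive-statistics checks.
"""
from __future__ import annotations

from typing import NamedTuple

RELATIVES = ("father", "mother", "sibling")

DISEASES = (
    "alzheimers_dementia",
    "bowel_cancer",
    "breast_cancer",
    "bronchitis_emphysema",
    "diabetes",
    "heart_disease",
    "high_blood_pressure",
    "lung_cancer",
    "parkinsons",
    "prostate_cancer",
    "severe_depression",
    "stroke",
)

#: diseases not applicable to a given relative
_EXCLUDED = {
    ("father", "breast_cancer"),
    ("mother", "prostate_cancer"),
}


class OutcomeSlot(NamedTuple):
    relative: str
    outcome: str
    kind: str  # 'disease' | 'vital_status' | 'age_at_death'


def default_catalog() -> list[OutcomeSlot]:
    """The 38 applicable (relative, outcome) slots."""
    slots = []
    for rel in RELATIVES:
        for d in DISEASES:
            if (rel, d) not in _EXCLUDED:
                slots.append(OutcomeSlot(rel, d, "disease"))
        if rel in ("father", "mother"):
            slots.append(OutcomeSlot(rel, "alive", "vital_status"))
            slots.append(OutcomeSlot(rel, "age_at_death", "age_at_death"))
    return slots


#: (relative, outcome) -> (cases, denominator), self-reported at enrolment
FAMILY_HISTORY_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("father", "alive"): (103_919, 450_333),
    ("mother", "alive"): (180_472, 454_999),
    ("father", "alzheimers_dementia"): (19_255, 399_793),
    ("mother", "alzheimers_dementia"): (36_548, 423_738),
    ("sibling", "alzheimers_dementia"): (2_094, 361_264),
    ("father", "bowel_cancer"): (23_883, 399_920),
    ("mother", "bowel_cancer"): (22_028, 423_135),
    ("sibling", "bowel_cancer"): (8_920, 361_508),
    ("mother", "breast_cancer"): (35_102, 423_458),
    ("sibling", "breast_cancer"): (16_586, 361_809),
    ("father", "bronchitis_emphysema"): (46_263, 402_389),
    ("mother", "bronchitis_emphysema"): (25_314, 423_692),
    ("sibling", "bronchitis_emphysema"): (10_325, 361_823),
    ("father", "diabetes"): (38_850, 400_687),
    ("mother", "diabetes"): (40_091, 423_892),
    ("sibling", "diabetes"): (31_073, 362_826),
    ("father", "heart_disease"): (133_320, 407_557),
    ("mother", "heart_disease"): (85_620, 426_240),
    ("sibling", "heart_disease"): (37_858, 363_542),
    ("father", "high_blood_pressure"): (91_242, 402_899),
    ("mother", "high_blood_pressure"): (130_948, 426_391),
    ("sibling", "high_blood_pressure"): (77_059, 364_661),
    ("father", "lung_cancer"): (37_443, 401_624),
    ("mother", "lung_cancer"): (17_566, 423_258),
    ("sibling", "lung_cancer"): (8_199, 361_586),
    ("father", "parkinsons"): (10_106, 399_089),
    ("mother", "parkinsons"): (6_998, 422_464),
    ("sibling", "parkinsons"): (2_005, 361_199),
    ("father", "prostate_cancer"): (30_945, 399_670),
    ("sibling", "prostate_cancer"): (5_952, 361_394),
    ("father", "severe_depression"): (15_430, 399_499),
    ("mother", "severe_depression"): (28_351, 423_217),
    ("sibling", "severe_depression"): (26_368, 362_315),
    ("father", "stroke"): (62_810, 402_616),
    ("mother", "stroke"): (60_880, 424_977),
    ("sibling", "stroke"): (12_031, 361_925),
}

#: mean (SD, n) of observed age at death among deceased parents
AGE_AT_DEATH = {
    "father": {"mean": 70.9, "sd": 13.1, "n": 341_118},
    "mother": {"mean": 75.7, "sd": 13.3, "n": 273_111},
}


def prevalence(relative: str, outcome: str) -> float:
    """Fraction of reports positive for the slot (cases / denominator)."""
    cases, total = FAMILY_HISTORY_COUNTS[(relative, outcome)]
    return cases / total
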