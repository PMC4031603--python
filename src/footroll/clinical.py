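"""Clinical instruments for diabetic-polyneuropathy trials.

Covers score storage and validation for the Michigan Neuropathy Screening
Instrument (MNSI: a 13-point symptom questionnaire and a 10-point foot
physical assessment in 0.5 steps), the Activities-specific Balance
Confidence (ABC) scale, manual muscle-function grading on the 0–5 ordinal
scale, 30-second functional repetition tests with their four-level
classification, and the trial eligibility screen.  Item-level MNSI
scoring is out of scope: totals are stored and validated as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

__all__ = [
    "MUSCLES",
    "FUNCTIONAL_MOVEMENTS",
    "FunctionalClass",
    "ClinicalRecord",
    "EligibilityProfile",
    "IncompleteProfileError",
    "classify_functional_test",
    "check_eligibility",
    "validate_clinical_record",
]

#: Muscles assessed by manual function testing.
MUSCLES = (
    "triceps_surae",
    "tibialis_anterior",
    "interosseous",
    "lumbrical",
    "flexor_hallucis_brevis",
    "flexor_digitorum_brevis",
    "extensor_hallucis_longus_brevis",
    "extensor_digitorum_longus_brevis",
)

#: Movements of the 30-second functional repetition tests.
FUNCTIONAL_MOVEMENTS = ("ankle_flexion", "ankle_extension",
                        "toes_flexion", "toes_extension")


class FunctionalClass(IntEnum):
    """Ordered functional categories from repetition counts."""

    NOT_FUNCTIONAL = 0
    BARELY_FUNCTIONAL = 1
    REASONABLY_FUNCTIONAL = 2
    FUNCTIONAL = 3


class IncompleteProfileError(ValueError):
    """Eligibility profile is missing a required field."""


def classify_functional_test(repetitions: int) -> FunctionalClass:
    """Classify a 30-second repetition count.

    0 → not functional; 1–4 → barely functional; 5–9 → reasonably
    functional; 10–15 → functional.  Counts above 15 also classify as
    functional: the scale tops out at 15 but fast subjects can exceed it
    in 30 s.
    """
    if repetitions < 0:
        raise ValueError("repetition count must be >= 0")
    if repetitions == 0:
        return FunctionalClass.NOT_FUNCTIONAL
    if repetitions <= 4:
        return FunctionalClass.BARELY_FUNCTIONAL
    if repetitions <= 9:
        return FunctionalClass.REASONABLY_FUNCTIONAL
    return FunctionalClass.FUNCTIONAL


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject × timepoint set of clinical scores."""

    mnsi_questionnaire: float           # 0–13
    mnsi_physical: float                # 0–10 in 0.5 steps
    abc: float                          # % confidence, 0–100
    muscle_grades: dict[str, int] = field(default_factory=dict)       # 0–5
    functional_repetitions: dict[str, int] = field(default_factory=dict)


def validate_clinical_record(record: ClinicalRecord) -> list[str]:
    """Range-check every score; returns a list of violations (empty iff valid)."""
    v: list[str] = []
    if not 0 <= record.mnsi_questionnaire <= 13:
        v.append(f"MNSI questionnaire {record.mnsi_questionnaire} exceeds 13 "
                 "or is negative")
    if not 0 <= record.mnsi_physical <= 10:
        v.append(f"MNSI physical {record.mnsi_physical} outside 0-10")
    elif (2 * record.mnsi_physical) % 1 != 0:
        v.append(f"MNSI physical {record.mnsi_physical} not a 0.5 step")
    if not 0 <= record.abc <= 100:
        v.append(f"ABC score {record.abc} outside 0-100")
    for muscle, grade in record.muscle_grades.items():
        if muscle not in MUSCLES:
            v.append(f"unknown muscle {muscle!r}")
        if not 0 <= grade <= 5:
            v.append(f"{muscle}: grade {grade} outside 0-5")
    for movement, reps in record.functional_repetitions.items():
        if movement not in FUNCTIONAL_MOVEMENTS:
            v.append(f"unknown movement {movement!r}")
        if reps < 0:
            v.append(f"{movement}: negative repetition count {reps}")
    return v


@dataclass(frozen=True)
class EligibilityProfile:
    """Candidate profile for the trial eligibility screen."""

    age: float                       # years
    bmi: float                       # kg/m²
    diabetes_duration: float         # years since diagnosis
    mnsi_questionnaire: float
    mnsi_physical: float
    impaired_vibration: bool
    ulceration_history: bool = False
    amputation_history: bool = False
    other_exclusions: tuple[str, ...] = ()   # e.g. severe retinopathy


_REQUIRED = ("age", "bmi", "diabetes_duration", "mnsi_questionnaire",
             "mnsi_physical", "impaired_vibration")


def check_eligibility(profile: EligibilityProfile) -> tuple[bool, list[str]]:
    """Screen a candidate; returns (eligible, reasons for every failure).

    Eligible iff: age 45–65 y, BMI 18.5–29.9 kg/m² (normal/overweight),
    diabetes diagnosed ≥ 7 y, MNSI questionnaire > 2 (of 13), MNSI
    physical > 1 (of 10) with impaired vibration perception, and no
    ulceration/amputation history or listed exclusions.  All failed
    criteria are reported, not just the first.
    """
    for name in _REQUIRED:
        if getattr(profile, name) is None:
            raise IncompleteProfileError(f"missing required field {name!r}")
    reasons: list[str] = []
    if not 45 <= profile.age <= 65:
        reasons.append(f"age {profile.age:g} outside 45-65 years")
    if not 18.5 <= profile.bmi <= 29.9:
        reasons.append(f"BMI {profile.bmi:g} out of 18.5-29.9")
    if profile.diabetes_duration < 7:
        reasons.append(f"diabetes duration {profile.diabetes_duration:g} y < 7 y")
    if not profile.mnsi_questionnaire > 2:
        reasons.append(f"MNSI questionnaire {profile.mnsi_questionnaire:g} "
                       "not > 2")
    if not profile.mnsi_physical > 1:
        reasons.append(f"MNSI physical {profile.mnsi_physical:g} not > 1")
    if not profile.impaired_vibration:
        reasons.append("vibration perception not impaired")
    if profile.ulceration_history:
        reasons.append("history of plantar ulceration")
    if profile.amputation_history:
        reasons.append("history of foot amputation")
    for excl in profile.other_exclusions:
        reasons.append(f"exclusion: {excl}")
    return (not reasons, reasons)
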