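"""Imaging strategies for lymphoma work-up and their realized exposure histories.

Two built-in protocols are encoded:

* paediatric Hodgkin's disease (HD, diagnosis before 18 y): a 5-year
  programme of 12 CTs (1 initial whole-body, 2 whole-body during therapy,
  7 neck-chest follow-ups at 3–24 months, 2 whole-body at 36 and 60 months)
  and 2 whole-body PETs (at diagnosis and directly after therapy);
* adult diffuse large B-cell lymphoma (DLBCL): 7 whole-body CTs and 1 PET
  over 2.5 years (initial CT, 2 therapy CTs plus the PET, follow-up CTs at
  6, 12, 18 and 24 months).

Chest radiography and ultrasound are omitted (negligible or no radiation
exposure).  Realizing a protocol for a patient turns each scheduled exam
into an exposure event carrying the age-interpolated organ-dose vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .dosimetry import (
    DEFAULT_ADULT_ANCHOR_AGE,
    ExamType,
    OrganDoseTable,
    OrganDoseVector,
    interpolate_doses,
)

__all__ = [
    "PatientProfile",
    "ScheduledExam",
    "ImagingProtocol",
    "ExposureEvent",
    "ExposureHistory",
    "standard_protocol",
    "load_protocol",
    "realize",
    "cumulative_effective_dose",
]


@dataclass(frozen=True)
class PatientProfile:
    sex: str  # "male" | "female"
    age_at_diagnosis_years: float
    disease: str  # "HD" | "DLBCL"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.disease not in ("HD", "DLBCL"):
            raise ValueError(f"disease must be 'HD' or 'DLBCL', got {self.disease!r}")
        if self.age_at_diagnosis_years < 0:
            raise ValueError("age_at_diagnosis_years must be non-negative")
        if self.disease == "HD" and self.age_at_diagnosis_years >= 18:
            raise ValueError("HD profiles are paediatric (age at diagnosis < 18 y)")
        if self.disease == "DLBCL" and self.age_at_diagnosis_years < 18:
            raise ValueError("DLBCL profiles are adult (age at diagnosis >= 18 y)")


@dataclass(frozen=True)
class ScheduledExam:
    exam: ExamType
    offset_months: float

    def __post_init__(self) -> None:
        if self.offset_months < 0:
            raise ValueError("offset_months must be non-negative")


@dataclass(frozen=True)
class ImagingProtocol:
    disease: str
    exams: tuple[ScheduledExam, ...]


@dataclass(frozen=True)
class ExposureEvent:
    age_at_exposure_years: float
    organ_doses: OrganDoseVector


#: An exposure history is the ordered (nondecreasing age) event list.
ExposureHistory = tuple[ExposureEvent, ...]

# Therapy-phase offsets (months): CTs at 2 and 4; the post-therapy PET at 6
# for children, the therapy PET at 3 for adults.  The exact placement only
# shifts paediatric interpolated doses by well under 1 mSv.
_THERAPY_CT_MONTHS = (2.0, 4.0)
_HD_POST_THERAPY_PET_MONTH = 6.0
_DLBCL_THERAPY_PET_MONTH = 3.0
_HD_FOLLOWUP_MONTHS = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 24.0, 36.0, 60.0)
_DLBCL_FOLLOWUP_MONTHS = (6.0, 12.0, 18.0, 24.0)


def standard_protocol(disease: str, swap_followup: bool = False) -> ImagingProtocol:
    """The built-in imaging strategy for ``"HD"`` (children) or ``"DLBCL"`` (adults).

    For HD the follow-up CTs at 3–24 months are neck-chest and those at 36
    and 60 months whole-body.  ``swap_followup=True`` selects the variant
    with 5 neck-chest and the remainder whole-body follow-ups (the two
    published descriptions of the strategy disagree on this split; the
    default reproduces the published cumulative doses).
    """
    exams: list[ScheduledExam] = []
    if disease == "HD":
        exams.append(ScheduledExam(ExamType.WB_CT, 0.0))
        exams.append(ScheduledExam(ExamType.PET, 0.0))
        for m in _THERAPY_CT_MONTHS:
            exams.append(ScheduledExam(ExamType.WB_CT, m))
        exams.append(ScheduledExam(ExamType.PET, _HD_POST_THERAPY_PET_MONTH))
        if not swap_followup:
            neck_chest = [m for m in _HD_FOLLOWUP_MONTHS if m <= 24.0]
        else:
            neck_chest = [m for m in _HD_FOLLOWUP_MONTHS if m <= 15.0]
        for m in _HD_FOLLOWUP_MONTHS:
            exam = ExamType.NECK_CHEST_CT if m in neck_chest else ExamType.WB_CT
            exams.append(ScheduledExam(exam, m))
    elif disease == "DLBCL":
        exams.append(ScheduledExam(ExamType.WB_CT, 0.0))
        for m in _THERAPY_CT_MONTHS:
            exams.append(ScheduledExam(ExamType.WB_CT, m))
        exams.append(ScheduledExam(ExamType.PET, _DLBCL_THERAPY_PET_MONTH))
        for m in _DLBCL_FOLLOWUP_MONTHS:
            exams.append(ScheduledExam(ExamType.WB_CT, m))
    else:
        raise ValueError(f"unknown disease {disease!r}")
    exams.sort(key=lambda e: e.offset_months)
    return ImagingProtocol(disease=disease, exams=tuple(exams))


def load_protocol(path: str, disease: str) -> ImagingProtocol:
    """Read a user-defined protocol: a YAML list of ``{exam, offset_months}``."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    exams = tuple(
        sorted(
            (ScheduledExam(ExamType(e["exam"]), float(e["offset_months"])) for e in entries),
            key=lambda e: e.offset_months,
        )
    )
    return ImagingProtocol(disease=disease, exams=exams)


def realize(
    protocol: ImagingProtocol,
    patient: PatientProfile,
    dose_table: OrganDoseTable,
    adult_anchor_age: float = DEFAULT_ADULT_ANCHOR_AGE,
) -> ExposureHistory:
    """Turn a protocol into the patient's exposure history.

    Each scheduled exam occurs at ``age_at_diagnosis + offset/12`` years and
    carries the dose vector interpolated at that age.
    """
    if protocol.disease != patient.disease:
        raise ValueError(
            f"protocol is for {protocol.disease}, patient has {patient.disease}"
        )
    events = []
    for sched in protocol.exams:
        age = patient.age_at_diagnosis_years + sched.offset_months / 12.0
        doses = interpolate_doses(dose_table, sched.exam, age, adult_anchor_age)
        events.append(ExposureEvent(age_at_exposure_years=age, organ_doses=doses))
    return tuple(events)


def cumulative_effective_dose(history: ExposureHistory) -> tuple[float, int]:
    """Sum of per-event effective doses, as ``(raw_mSv, rounded_mSv)``."""
    raw = sum(e.organ_doses.effective_dose_mSv for e in history)
    return raw, int(round(raw))
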