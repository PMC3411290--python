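"""Per-examination organ and effective doses for lymphoma imaging.

The dosimetric input surface is a table of organ doses, effective dose and
(for CT) total-body dose, in mSv, for three examination types — whole-body CT
(neck-chest-abdomen), CT of neck and chest, and whole-body 18F-FDG PET — on
six phantom age categories: newborn, 1, 5, 10, 15 years and adult.  The
bundled table was obtained from Monte Carlo CT dosimetry on MIRD V
hermaphrodite phantoms and ICRP per-MBq PET dose coefficients; this module
only consumes such tables, it does not compute them.

Doses for intermediate patient ages are produced by component-wise linear
interpolation between the phantom anchors, with the adult anchor placed (by
default) at 20 years — the age by which the 74-kg adult reference body size
is reached (the 15-year phantom weighs only 56.8 kg) — and a plateau at
adult values beyond it.  The anchor age is configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExamType",
    "ORGANS",
    "PHANTOM_AGES",
    "OrganDoseVector",
    "OrganDoseTable",
    "load_dose_table",
    "interpolate_doses",
    "pet_administered_activity",
    "DEFAULT_ADULT_ANCHOR_AGE",
]


class ExamType(str, enum.Enum):
    """Examination types with tabulated doses.

    ``WB_CT`` is the whole-body CT covering neck, chest and abdomen;
    ``NECK_CHEST_CT`` covers neck and chest only; ``PET`` is a whole-body
    18F-FDG PET.
    """

    WB_CT = "WB_CT"
    NECK_CHEST_CT = "NECK_CHEST_CT"
    PET = "PET"


#: The twelve organ/tissue rows of the dose table (risk-model dose sites).
ORGANS: tuple[str, ...] = (
    "bone_marrow",
    "stomach",
    "colon",
    "liver",
    "lung",
    "breast",
    "prostate",
    "uterus",
    "ovary",
    "bladder",
    "other_solid",
    "thyroid",
)

#: Phantom age categories, in years; "adult" is handled separately.
PHANTOM_AGES: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 15.0)

#: Age (years) at which the adult phantom doses are anchored by default.
DEFAULT_ADULT_ANCHOR_AGE: float = 20.0

_AGE_LABELS = ("0", "1", "5", "10", "15", "adult")

#: Fixed administered 18F-FDG activities (MBq) per phantom age category,
#: corresponding to 3 MBq/kg at the phantom reference weights.
PET_ACTIVITY_MBQ: Mapping[str, float] = {
    "0": 10.0,
    "1": 30.0,
    "5": 60.0,
    "10": 100.0,
    "15": 170.0,
    "adult": 220.0,
}


@dataclass(frozen=True)
class OrganDoseVector:
    """Doses (mSv) delivered by a single examination.

    ``organ_doses`` maps every organ in :data:`ORGANS` to its dose.
    ``total_body_mSv`` is tabulated for CT only and is ``None`` for PET
    (absent, not zero — it is never used downstream).
    """

    organ_doses: Mapping[str, float]
    effective_dose_mSv: float
    total_body_mSv: float | None = None

    def __post_init__(self) -> None:
        missing = [o for o in ORGANS if o not in self.organ_doses]
        if missing:
            raise ValueError(f"organ doses missing for: {missing}")
        vals = list(self.organ_doses.values()) + [self.effective_dose_mSv]
        if self.total_body_mSv is not None:
            vals.append(self.total_body_mSv)
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("doses must be finite")
        if np.any(arr < 0):
            raise ValueError("doses must be non-negative")

    def scaled(self, k: float) -> "OrganDoseVector":
        """Return the vector with every component multiplied by ``k``."""
        return OrganDoseVector(
            organ_doses={o: k * v for o, v in self.organ_doses.items()},
            effective_dose_mSv=k * self.effective_dose_mSv,
            total_body_mSv=None if self.total_body_mSv is None else k * self.total_body_mSv,
        )


class OrganDoseTable:
    """Complete (exam type × phantom age) grid of :class:`OrganDoseVector`."""

    def __init__(self, cells: Mapping[tuple[ExamType, str], OrganDoseVector]):
        for exam in ExamType:
            for age in _AGE_LABELS:
                if (exam, age) not in cells:
                    raise ValueError(f"dose table incomplete: missing ({exam.value}, {age})")
        self._cells = dict(cells)

    def __getitem__(self, key: tuple[ExamType, str]) -> OrganDoseVector:
        exam, age = key
        return self._cells[(ExamType(exam), str(age))]

    def scaled(self, k: float) -> "OrganDoseTable":
        return OrganDoseTable({key: v.scaled(k) for key, v in self._cells.items()})


def _builtin_csv() -> Path:
    return Path(str(resources.files("lymphorad.data") / "imaging_doses.csv"))


def load_dose_table(source: str | Path = "builtin") -> OrganDoseTable:
    """Load and validate an organ-dose table.

    Parameters
    ----------
    source
        Path to a long-format CSV with columns ``exam_type, phantom_age,
        organ, dose_mSv``, or ``"builtin"`` for the bundled table.

    Raises
    ------
    ValueError
        On missing cells or organs, negative or non-finite doses, or a
        malformed file (the error names the offending row/column).
    """
    path = _builtin_csv() if source == "builtin" else Path(source)
    df = pd.read_csv(path, dtype={"phantom_age": str})
    expected_cols = {"exam_type", "phantom_age", "organ", "dose_mSv"}
    if not expected_cols.issubset(df.columns):
        raise ValueError(
            f"dose table {path} missing columns: {sorted(expected_cols - set(df.columns))}"
        )
    cells: dict[tuple[ExamType, str], OrganDoseVector] = {}
    for (exam_s, age), grp in df.groupby(["exam_type", "phantom_age"]):
        try:
            exam = ExamType(exam_s)
        except ValueError as err:
            raise ValueError(f"unknown exam_type {exam_s!r} in {path}") from err
        if age not in _AGE_LABELS:
            raise ValueError(f"unknown phantom_age {age!r} in {path}")
        doses = dict(zip(grp["organ"], grp["dose_mSv"].astype(float)))
        if "effective_dose" not in doses:
            raise ValueError(f"({exam.value}, {age}): missing 'effective_dose' row")
        missing = [o for o in ORGANS if o not in doses]
        if missing:
            raise ValueError(f"({exam.value}, {age}): missing organ rows {missing}")
        cells[(exam, age)] = OrganDoseVector(
            organ_doses={o: doses[o] for o in ORGANS},
            effective_dose_mSv=doses["effective_dose"],
            total_body_mSv=doses.get("total_body"),
        )
    return OrganDoseTable(cells)


def interpolate_doses(
    table: OrganDoseTable,
    exam: ExamType,
    age_years: float,
    adult_anchor_age: float = DEFAULT_ADULT_ANCHOR_AGE,
) -> OrganDoseVector:
    """Dose vector for ``exam`` at an arbitrary patient age.

    Component-wise linear interpolation between the phantom anchors at 0, 1,
    5, 10 and 15 years and the adult anchor at ``adult_anchor_age`` (default
    20 y); adult values apply as a plateau beyond the adult anchor.  Exact at
    every anchor.
    """
    if age_years < 0:
        raise ValueError("age_years must be non-negative")
    exam = ExamType(exam)
    anchors = list(PHANTOM_AGES) + [float(adult_anchor_age)]
    vectors = [table[(exam, lbl)] for lbl in _AGE_LABELS]
    if age_years >= adult_anchor_age:
        return vectors[-1]
    xs = np.asarray(anchors)

    def interp(component: list[float]) -> float:
        return float(np.interp(age_years, xs, np.asarray(component, dtype=float)))

    organ_doses = {
        o: interp([v.organ_doses[o] for v in vectors]) for o in ORGANS
    }
    eff = interp([v.effective_dose_mSv for v in vectors])
    tb_vals = [v.total_body_mSv for v in vectors]
    tb = None if any(t is None for t in tb_vals) else interp(tb_vals)  # type: ignore[arg-type]
    return OrganDoseVector(organ_doses=organ_doses, effective_dose_mSv=eff, total_body_mSv=tb)


def pet_administered_activity(age_category: str) -> float:
    """Administered 18F-FDG activity (MBq) for a phantom age category.

    Categories are ``"0"``, ``"1"``, ``"5"``, ``"10"``, ``"15"`` and
    ``"adult"`` (3 MBq/kg at the reference weights: 10/30/60/100/170 MBq for
    the paediatric categories, 220 MBq for adults).
    """
    key = str(age_category)
    if key not in PET_ACTIVITY_MBQ:
        raise ValueError(f"unknown phantom age category: {age_category!r}")
    return PET_ACTIVITY_MBQ[key]
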