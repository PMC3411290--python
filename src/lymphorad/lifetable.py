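"""Cohort life tables under background, radiation-induced and disease hazards.

The cohort starts at the age at diagnosis with survivorship 1 and is
followed in fixed steps (default one year) to ``max_age``.  Within each
interval the total hazard — background all-cause mortality, radiation-
induced excess mortality from the accumulated exposure history, and the
disease-related excess hazard — is treated as constant at its midpoint
value, so the interval death probability is ``q = 1 - exp(-mu * dt)``.
Deaths are attributed to the three causes in proportion to their hazard
contributions (the standard competing-risks partition), which yields:

* REID, the fraction of the cohort eventually dying of radiation-induced
  cancer (the sum of radiation-attributed deaths);
* life expectancy at diagnosis, by trapezoidal person-year accumulation
  (deaths counted for half an interval, survivors at ``max_age`` for none);
* survival at a fixed horizon after diagnosis;
* reductions of life expectancy, as differences against counterfactual
  tables with the radiation or disease hazard removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beir7 import (
    ERRParameterSet,
    RiskConfig,
    excess_mortality_rate,
    load_err_parameters,
)
from .dosimetry import DEFAULT_ADULT_ANCHOR_AGE, OrganDoseTable
from .mortality import (
    DLBCL_SURVIVAL,
    HD_SURVIVAL,
    DiseaseHazard,
    RateTable,
    calibrate_disease_hazard,
)
from .schedule import (
    ExposureHistory,
    PatientProfile,
    realize,
    standard_protocol,
)

__all__ = [
    "LifeTableResult",
    "CohortSummary",
    "DAYS_PER_YEAR",
    "HD_COHORT_AGES",
    "DLBCL_COHORT_AGES",
    "build_life_table",
    "reid",
    "delta_life_expectancy",
    "summarize_cohort",
]

DAYS_PER_YEAR = 365.25

#: Ages at diagnosis of the study cohorts.
HD_COHORT_AGES: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 15.0)
DLBCL_COHORT_AGES: tuple[float, ...] = (55.0, 65.0, 75.0)

CAUSES = ("background", "radiation", "disease")


@dataclass(frozen=True)
class LifeTableResult:
    """Per-interval decomposition of a cohort life table plus summaries."""

    start_age: float
    step_years: float
    ages: np.ndarray  # interval start ages, length n
    survivorship: np.ndarray  # l at interval starts plus final value, length n+1
    deaths: np.ndarray  # total deaths per interval, length n
    deaths_by_cause: Mapping[str, np.ndarray]
    life_expectancy_years: float

    @property
    def reid(self) -> float:
        """Fraction of the cohort dying of radiation-induced cancer."""
        return float(np.sum(self.deaths_by_cause["radiation"]))

    def survival_at(self, years_after_start: float) -> float:
        """Survivorship ``years_after_start`` after the cohort start."""
        grid = np.append(self.ages - self.start_age, len(self.ages) * self.step_years)
        return float(np.interp(years_after_start, grid, self.survivorship))

    def validate_conservation(self, tol: float = 1e-9) -> None:
        total = float(np.sum(self.deaths)) + float(self.survivorship[-1])
        if abs(total - 1.0) > tol:
            raise AssertionError(f"cohort not conserved: {total}")
        attributed = sum(np.sum(self.deaths_by_cause[c]) for c in CAUSES)
        if abs(attributed - float(np.sum(self.deaths))) > tol:
            raise AssertionError("attributed deaths do not sum to total deaths")


def build_life_table(
    patient: PatientProfile,
    history: ExposureHistory,
    background: RateTable,
    cancer_tables: Mapping[str, RateTable],
    err_params: ERRParameterSet | None = None,
    risk_config: RiskConfig = RiskConfig(),
    disease_hazard: DiseaseHazard | None = None,
    include_radiation: bool = True,
    max_age: float = 110.0,
    step_years: float = 1.0,
) -> LifeTableResult:
    """Run the cohort life table for one patient category.

    ``cancer_tables`` maps every risk site (solid sites plus ``"leukemia"``)
    to its baseline cancer-mortality :class:`RateTable`.  The three modes of
    the analysis are selected by ``include_radiation`` and
    ``disease_hazard`` (``None`` disables disease mortality).
    """
    if err_params is None:
        err_params = load_err_parameters()
    start = patient.age_at_diagnosis_years
    if max_age > background.max_age:
        raise ValueError(
            f"max_age {max_age} beyond background table range {background.max_age}"
        )
    n = int(math.ceil((max_age - start) / step_years - 1e-12))
    ages = start + step_years * np.arange(n)
    sex = patient.sex
    h = step_years

    l = np.empty(n + 1)
    l[0] = 1.0
    deaths = np.zeros(n)
    by_cause = {c: np.zeros(n) for c in CAUSES}
    person_years = 0.0
    for k in range(n):
        a_mid = ages[k] + h / 2.0
        mu_bg = background.rate(a_mid, sex)
        if include_radiation and history:
            baseline = {
                site: cancer_tables[site].rate(a_mid, sex)
                for site in cancer_tables
            }
            mu_rad = excess_mortality_rate(
                a_mid, sex, history, baseline, err_params, risk_config
            )
        else:
            mu_rad = 0.0
        t_mid = a_mid - start
        mu_dis = disease_hazard(t_mid) if disease_hazard is not None else 0.0
        mu = mu_bg + mu_rad + mu_dis
        q = 1.0 - math.exp(-mu * h)
        d = l[k] * q
        deaths[k] = d
        if mu > 0:
            by_cause["background"][k] = d * mu_bg / mu
            by_cause["radiation"][k] = d * mu_rad / mu
            by_cause["disease"][k] = d * mu_dis / mu
        person_years += h * l[k] * (1.0 - q / 2.0)
        l[k + 1] = l[k] - d

    return LifeTableResult(
        start_age=start,
        step_years=h,
        ages=ages,
        survivorship=l,
        deaths=deaths,
        deaths_by_cause=by_cause,
        life_expectancy_years=person_years,
    )


def reid(result: LifeTableResult) -> float:
    """Risk of exposure-induced death: total radiation-attributed deaths."""
    return result.reid


def delta_life_expectancy(
    full: LifeTableResult, counterfactual: LifeTableResult
) -> float:
    """Reduction of life expectancy (days) caused by the removed hazard."""
    return (
        counterfactual.life_expectancy_years - full.life_expectancy_years
    ) * DAYS_PER_YEAR


@dataclass(frozen=True)
class CohortSummary:
    """Per-category life-table estimators plus unweighted sex-wise averages.

    ``table`` has one row per (sex, age at diagnosis, corrected) with the
    published-table estimators; ``averages`` holds arithmetic means over the
    age categories, by sex and correction mode.
    """

    disease: str
    table: pd.DataFrame
    averages: pd.DataFrame
    results: Mapping[tuple[str, float, str], LifeTableResult] = field(repr=False, default_factory=dict)


def summarize_cohort(
    disease: str,
    background: RateTable,
    cancer_tables: Mapping[str, RateTable],
    dose_table: OrganDoseTable,
    err_params: ERRParameterSet | None = None,
    risk_config: RiskConfig = RiskConfig(),
    sexes: Sequence[str] = ("male", "female"),
    ages: Sequence[float] | None = None,
    adult_anchor_age: float = DEFAULT_ADULT_ANCHOR_AGE,
    max_age: float = 110.0,
    step_years: float = 1.0,
) -> CohortSummary:
    """Life-table risk summary over the study's patient categories.

    For each (sex, age at diagnosis) four life tables are run — background
    only, with radiation, with disease, and with both — yielding the
    corrected (disease mortality included) and uncorrected estimators:
    fraction of radiation-induced deaths, life expectancy at diagnosis,
    radiation-/disease-related/total reductions of life expectancy, and
    survival at the disease horizon (10 y for HD, 5 y for DLBCL).
    """
    if ages is None:
        ages = HD_COHORT_AGES if disease == "HD" else DLBCL_COHORT_AGES
    if err_params is None:
        err_params = load_err_parameters()
    spec = HD_SURVIVAL if disease == "HD" else DLBCL_SURVIVAL
    horizon = spec.horizon_years
    dis_hazard = calibrate_disease_hazard(spec)
    protocol = standard_protocol(disease)

    rows = []
    results: dict[tuple[str, float, str], LifeTableResult] = {}
    for sex in sexes:
        for age in ages:
            patient = PatientProfile(sex=sex, age_at_diagnosis_years=age, disease=disease)
            history = realize(protocol, patient, dose_table, adult_anchor_age)

            def run(rad: bool, dis: bool) -> LifeTableResult:
                return build_life_table(
                    patient,
                    history,
                    background,
                    cancer_tables,
                    err_params=err_params,
                    risk_config=risk_config,
                    disease_hazard=dis_hazard if dis else None,
                    include_radiation=rad,
                    max_age=max_age,
                    step_years=step_years,
                )

            lt_bg = run(False, False)
            lt_rad = run(True, False)
            lt_dis = run(False, True)
            lt_full = run(True, True)
            results[(sex, age, "background")] = lt_bg
            results[(sex, age, "radiation")] = lt_rad
            results[(sex, age, "disease")] = lt_dis
            results[(sex, age, "full")] = lt_full

            for corrected, lt, lt_norad, lt_nodis, lt_none in (
                (False, lt_rad, lt_bg, lt_rad, lt_bg),
                (True, lt_full, lt_dis, lt_rad, lt_bg),
            ):
                rows.append(
                    {
                        "disease": disease,
                        "sex": sex,
                        "age_at_diagnosis": age,
                        "corrected": corrected,
                        "reid": lt.reid,
                        "life_expectancy_years": lt.life_expectancy_years,
                        "dle_radiation_days": delta_life_expectancy(lt, lt_norad),
                        "dle_disease_days": delta_life_expectancy(lt, lt_nodis)
                        if corrected
                        else float("nan"),
                        "dle_total_days": delta_life_expectancy(lt, lt_none),
                        "survival_at_horizon": lt.survival_at(horizon),
                    }
                )

    table = pd.DataFrame(rows)
    averages = (
        table.groupby(["sex", "corrected"], as_index=False)
        .agg(
            reid=("reid", "mean"),
            life_expectancy_years=("life_expectancy_years", "mean"),
            dle_radiation_days=("dle_radiation_days", "mean"),
            dle_disease_days=("dle_disease_days", "mean"),
            dle_total_days=("dle_total_days", "mean"),
            survival_at_horizon=("survival_at_horizon", "mean"),
        )
        .assign(disease=disease)
    )
    return CohortSummary(disease=disease, table=table, averages=averages, results=results)
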