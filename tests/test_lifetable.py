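"""Cohort life-table construction, death attribution and summary estimators."""

import math

import numpy as np
import pytest

from lymphorad.beir7 import RiskConfig
from lymphorad.lifetable import (
    build_life_table,
    delta_life_expectancy,
    reid,
    summarize_cohort,
)
from lymphorad.mortality import DiseaseHazard, RateTable, calibrate_disease_hazard
from lymphorad.mortality import HD_SURVIVAL
from lymphorad.schedule import PatientProfile, realize, standard_protocol
from lymphorad.synthetic import RISK_SITES


def _flat_tables(mu, max_age=110, cancer_rate=0.0):
    rates = {"male": np.full(max_age + 1, mu), "female": np.full(max_age + 1, mu)}
    background = RateTable(rates=rates)
    cancer = {
        site: RateTable(
            rates={
                "male": np.full(max_age + 1, cancer_rate),
                "female": np.full(max_age + 1, cancer_rate),
            },
            site=site,
        )
        for site in RISK_SITES
    }
    return background, cancer


def _patient(age=60.0, sex="male", disease="DLBCL"):
    return PatientProfile(sex=sex, age_at_diagnosis_years=age, disease=disease)


def test_background_only_table_has_zero_reid():
    background, cancer = _flat_tables(0.02)
    result = build_life_table(
        _patient(), (), background, cancer, include_radiation=False
    )
    assert reid(result) == 0.0
    result.validate_conservation()
    # constant hazard m: LE = sum_k exp(-m k) (1 - q/2) in closed form
    m = 0.02
    n = 50
    q = 1 - math.exp(-m)
    expected = sum(math.exp(-m * k) * (1 - q / 2) for k in range(n))
    assert result.life_expectancy_years == pytest.approx(expected, rel=1e-12)


def test_constant_hazard_le_matches_fine_step_integration():
    """Brute-force numerical integration of the exponential lifetime oracle."""
    background, cancer = _flat_tables(0.05)
    annual = build_life_table(_patient(), (), background, cancer, include_radiation=False)
    # independent oracle: survival exp(-m t) integrated on a fine grid to age 110
    ts = np.linspace(0.0, 50.0, 200001)
    oracle = np.trapezoid(np.exp(-0.05 * ts), ts)
    assert annual.life_expectancy_years == pytest.approx(oracle, rel=2e-3)


def test_toy_worked_example_matches_golden_values(toy):
    patient = _patient(toy["start_age"])
    result = build_life_table(
        patient,
        toy["history"],
        toy["background"],
        toy["cancer_tables"],
        err_params=toy["err_params"],
        risk_config=toy["risk_config"],
        max_age=toy["max_age"],
    )
    result.validate_conservation(1e-12)
    assert reid(result) == pytest.approx(toy["golden"]["reid"], rel=1e-12)
    assert result.life_expectancy_years == pytest.approx(
        toy["golden"]["life_expectancy_years"], rel=1e-12
    )


def test_toy_with_disease_hazard_lowers_reid_to_golden(toy):
    patient = _patient(toy["start_age"])
    kwargs = dict(
        err_params=toy["err_params"],
        risk_config=toy["risk_config"],
        max_age=toy["max_age"],
    )
    plain = build_life_table(
        patient, toy["history"], toy["background"], toy["cancer_tables"], **kwargs
    )
    with_disease = build_life_table(
        patient,
        toy["history"],
        toy["background"],
        toy["cancer_tables"],
        disease_hazard=toy["disease_hazard"],
        **kwargs,
    )
    assert with_disease.reid < plain.reid
    assert with_disease.reid == pytest.approx(toy["golden"]["reid_with_disease"], rel=1e-12)


def test_toy_zero_dose_gives_zero_reid(toy):
    patient = _patient(toy["start_age"])
    history = tuple(
        type(e)(e.age_at_exposure_years, e.organ_doses.scaled(0.0)) for e in toy["history"]
    )
    result = build_life_table(
        patient,
        history,
        toy["background"],
        toy["cancer_tables"],
        err_params=toy["err_params"],
        risk_config=toy["risk_config"],
        max_age=toy["max_age"],
    )
    assert reid(result) == 0.0


def test_single_cause_radiation_reid_equals_total_deaths(toy):
    """With zero background the only hazard is radiation: REID = 1 - l(end)."""
    max_age = toy["max_age"]
    zero = RateTable(
        rates={"male": np.zeros(max_age + 1), "female": np.zeros(max_age + 1)}
    )
    result = build_life_table(
        _patient(toy["start_age"]),
        toy["history"],
        zero,
        toy["cancer_tables"],
        err_params=toy["err_params"],
        risk_config=toy["risk_config"],
        max_age=max_age,
    )
    assert reid(result) == pytest.approx(1.0 - result.survivorship[-1], rel=1e-12)


def test_three_age_life_table_hand_computed():
    """Hand 3-term competing-risks sum on flat hazards."""
    background, cancer = _flat_tables(0.1)
    mu_bg = 0.1
    h_d = 0.05
    disease = DiseaseHazard(rate_per_year=h_d)
    result = build_life_table(
        _patient(107.0),
        (),
        background,
        cancer,
        include_radiation=False,
        disease_hazard=disease,
        max_age=110.0,
    )
    mu = mu_bg + h_d
    q = 1 - math.exp(-mu)
    l = 1.0
    disease_deaths = 0.0
    for _ in range(3):
        disease_deaths += l * q * h_d / mu
        l *= 1 - q
    assert np.sum(result.deaths_by_cause["disease"]) == pytest.approx(disease_deaths, rel=1e-12)
    assert result.survivorship[-1] == pytest.approx(l, rel=1e-12)


def test_delta_life_expectancy_signs():
    background, cancer = _flat_tables(0.02)
    plain = build_life_table(_patient(), (), background, cancer, include_radiation=False)
    assert delta_life_expectancy(plain, plain) == 0.0
    hit = build_life_table(
        _patient(), (), background, cancer,
        include_radiation=False,
        disease_hazard=DiseaseHazard(rate_per_year=0.01),
    )
    assert delta_life_expectancy(hit, plain) > 0.0


def test_life_table_rejects_range_beyond_background():
    background, cancer = _flat_tables(0.02, max_age=80)
    with pytest.raises(ValueError, match="beyond"):
        build_life_table(_patient(), (), background, cancer, max_age=110.0)


@pytest.fixture(scope="module")
def hd_summary(background, cancer_tables, dose_table):
    return summarize_cohort("HD", background, cancer_tables, dose_table)


@pytest.fixture(scope="module")
def dlbcl_summary(background, cancer_tables, dose_table):
    return summarize_cohort("DLBCL", background, cancer_tables, dose_table)


def test_cohort_conservation_all_categories(hd_summary):
    for result in hd_summary.results.values():
        result.validate_conservation(1e-9)


def test_corrected_reid_below_uncorrected_everywhere(hd_summary, dlbcl_summary):
    for summary in (hd_summary, dlbcl_summary):
        t = summary.table.set_index(["sex", "age_at_diagnosis", "corrected"])
        for (sex, age), _ in t.groupby(level=[0, 1]):
            assert t.loc[(sex, age, True), "reid"] < t.loc[(sex, age, False), "reid"]
            assert (
                t.loc[(sex, age, True), "dle_radiation_days"]
                < t.loc[(sex, age, False), "dle_radiation_days"]
            )


def test_female_reid_at_least_male(hd_summary, dlbcl_summary):
    for summary in (hd_summary, dlbcl_summary):
        t = summary.table.pivot_table(
            index=["age_at_diagnosis", "corrected"], columns="sex", values="reid"
        )
        assert (t["female"] >= t["male"]).all()


def test_reid_monotone_under_dose_scaling(background, cancer_tables, dose_table, err_params):
    patient = _patient(65.0)
    history = realize(standard_protocol("DLBCL"), patient, dose_table)
    reids = []
    for k in (0.5, 1.0, 2.0):
        scaled = tuple(
            type(e)(e.age_at_exposure_years, e.organ_doses.scaled(k)) for e in history
        )
        result = build_life_table(
            patient, scaled, background, cancer_tables, err_params=err_params
        )
        reids.append(result.reid)
    assert reids[0] < reids[1] < reids[2]


def test_monthly_step_agrees_with_annual(background, cancer_tables, dose_table, err_params):
    patient = PatientProfile(sex="female", age_at_diagnosis_years=10.0, disease="HD")
    history = realize(standard_protocol("HD"), patient, dose_table)
    hazard = calibrate_disease_hazard(HD_SURVIVAL)
    annual = build_life_table(
        patient, history, background, cancer_tables,
        err_params=err_params, disease_hazard=hazard, step_years=1.0,
    )
    monthly = build_life_table(
        patient, history, background, cancer_tables,
        err_params=err_params, disease_hazard=hazard, step_years=1.0 / 12.0,
    )
    assert monthly.reid == pytest.approx(annual.reid, rel=5e-3)
    assert monthly.life_expectancy_years == pytest.approx(
        annual.life_expectancy_years, rel=5e-3
    )


def test_cohort_averages_are_unweighted_means(hd_summary):
    t = hd_summary.table
    avg = hd_summary.averages.set_index(["sex", "corrected"])
    sub = t[(t.sex == "female") & t.corrected]
    assert avg.loc[("female", True), "reid"] == pytest.approx(sub["reid"].mean())
    assert avg.loc[("female", True), "dle_radiation_days"] == pytest.approx(
        sub["dle_radiation_days"].mean()
    )


def test_single_category_average_equals_category(background, cancer_tables, dose_table):
    summary = summarize_cohort(
        "DLBCL", background, cancer_tables, dose_table, ages=[65.0], sexes=["male"]
    )
    t = summary.table[summary.table.corrected]
    avg = summary.averages
    row = avg[(avg.sex == "male") & avg.corrected]
    assert row["reid"].iloc[0] == pytest.approx(t["reid"].iloc[0])


def test_survival_at_horizon_interpolates(toy):
    result = build_life_table(
        _patient(toy["start_age"]),
        (),
        toy["background"],
        toy["cancer_tables"],
        include_radiation=False,
        max_age=toy["max_age"],
    )
    s1 = result.survival_at(1.0)
    assert s1 == pytest.approx(math.exp(-0.1), rel=1e-12)
    assert result.survival_at(0.0) == 1.0
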