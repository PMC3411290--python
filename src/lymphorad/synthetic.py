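"""Synthetic mortality inputs emulating the analysis' data requirements.

The risk analysis consumes two external tables that cannot be bundled:
European all-cause mortality by sex and age, and Euro-American baseline
cancer mortality by sex, age and site.  This module generates realistic
stand-ins so the whole pipeline runs self-contained:

* background all-cause mortality follows a Gompertz–Makeham hazard
  ``mu(a) = c + A * exp(B * a)`` per sex, with defaults calibrated so life
  expectancy at birth is 76 y (male) and 82 y (female) — the range spanned
  by recent European period tables;
* baseline cancer mortality per site follows a power-law-above-onset shape
  ``lambda(a) = scale * ((a - onset)/10) ** power``, with scales calibrated
  to plausible Euro-American lifetime site-mortality fractions (about 20%
  of male and 17% of female deaths from the modelled cancer sites) and
  constrained to stay below all-cause mortality at every age.

Everything generated here passes the same validators as user-supplied CSVs;
substituting genuine Eurostat / ICRP-format exports in the documented CSV
schema is the intended production path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .beir7 import (
    SOLID_SITES,
    ERRParameterSet,
    LeukemiaParams,
    RiskConfig,
    SolidSiteParams,
)
from .dosimetry import ORGANS, OrganDoseVector
from .mortality import DiseaseHazard, RateTable
from .schedule import ExposureEvent, ExposureHistory

__all__ = [
    "GompertzMakehamParams",
    "DEFAULT_BACKGROUND_PARAMS",
    "CancerSiteShape",
    "DEFAULT_CANCER_SHAPES",
    "make_background_table",
    "make_cancer_rate_tables",
    "make_toy_worked_example",
    "write_synthetic_inputs",
]

RISK_SITES: tuple[str, ...] = SOLID_SITES + ("leukemia",)


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Gompertz–Makeham hazard ``mu(a) = makeham_c + gompertz_a * exp(gompertz_b * a)``."""

    makeham_c: float  # age-independent hazard, /yr
    gompertz_a: float  # /yr
    gompertz_b: float  # /yr of age

    def __post_init__(self) -> None:
        if min(self.makeham_c, self.gompertz_a, self.gompertz_b) < 0:
            raise ValueError("Gompertz-Makeham parameters must be non-negative")

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.makeham_c + self.gompertz_a * np.exp(self.gompertz_b * np.asarray(age, dtype=float))


#: Calibrated so life expectancy at birth is ~76 y (male) / ~82 y (female),
#: with the Makeham floor matching European child/young-adult mortality
#: (~1.5-2 per 10,000 per year).
DEFAULT_BACKGROUND_PARAMS: Mapping[str, GompertzMakehamParams] = {
    "male": GompertzMakehamParams(makeham_c=2.0e-4, gompertz_a=4.51e-5, gompertz_b=0.092),
    "female": GompertzMakehamParams(makeham_c=1.5e-4, gompertz_a=1.36e-5, gompertz_b=0.101),
}


@dataclass(frozen=True)
class CancerSiteShape:
    """Power-law-above-onset baseline cancer mortality shape for one site/sex."""

    scale: float  # rate multiplier, /yr
    onset_age: float  # years
    power: float  # dimensionless

    def rate(self, age: np.ndarray | float) -> np.ndarray | float:
        x = np.clip((np.asarray(age, dtype=float) - self.onset_age) / 10.0, 0.0, None)
        return self.scale * x**self.power


def _shapes(
    onset: float, power: float, scale_m: float, scale_f: float
) -> dict[str, CancerSiteShape]:
    return {
        "male": CancerSiteShape(scale_m, onset, power),
        "female": CancerSiteShape(scale_f, onset, power),
    }


#: site -> sex -> shape.  Scales calibrated against the default background
#: tables to give plausible lifetime site-mortality fractions; sex-specific
#: sites carry zero scale for the other sex.
DEFAULT_CANCER_SHAPES: Mapping[str, Mapping[str, CancerSiteShape]] = {
    "lung": _shapes(35.0, 4.0, 9.95e-6, 3.72e-6),
    "stomach": _shapes(30.0, 4.0, 1.89e-6, 8.09e-7),
    "colon": _shapes(30.0, 4.0, 2.52e-6, 1.46e-6),
    "liver": _shapes(30.0, 3.5, 2.70e-6, 1.08e-6),
    "breast": _shapes(25.0, 2.5, 0.0, 1.90e-5),
    "prostate": _shapes(45.0, 5.0, 3.78e-6, 0.0),
    "uterus": _shapes(35.0, 3.0, 0.0, 2.79e-6),
    "ovary": _shapes(30.0, 3.0, 0.0, 3.94e-6),
    "bladder": _shapes(40.0, 4.5, 1.30e-6, 3.30e-7),
    "other_solid": _shapes(20.0, 3.0, 1.75e-5, 1.05e-5),
    "thyroid": _shapes(20.0, 2.0, 1.13e-6, 1.09e-6),
    "leukemia": _shapes(0.0, 2.0, 5.47e-6, 3.47e-6),
}


def make_background_table(
    params: Mapping[str, GompertzMakehamParams] = DEFAULT_BACKGROUND_PARAMS,
    max_age: int = 110,
    seed: int | None = None,
    noise_sigma: float = 0.02,
) -> RateTable:
    """All-cause mortality RateTable from Gompertz–Makeham hazards.

    Deterministic given ``params``; with a ``seed``, multiplicative
    log-normal noise (``sigma`` on the log scale) roughens the age profile
    the way empirical period tables are rough.
    """
    ages = np.arange(max_age + 1, dtype=float)
    rng = np.random.default_rng(seed) if seed is not None else None
    rates: dict[str, np.ndarray] = {}
    for sex, p in params.items():
        mu = np.asarray(p.hazard(ages), dtype=float)
        if rng is not None:
            mu = mu * np.exp(rng.normal(0.0, noise_sigma, size=mu.shape))
        rates[sex] = mu
    return RateTable(rates=rates)


def make_cancer_rate_tables(
    shapes: Mapping[str, Mapping[str, CancerSiteShape]] = DEFAULT_CANCER_SHAPES,
    background: RateTable | None = None,
) -> dict[str, RateTable]:
    """Per-site baseline cancer-mortality tables on the background age grid.

    Raises if the summed site rates reach the all-cause rate at any age
    (cancer mortality must be a strict subset of all-cause mortality).
    """
    if background is None:
        background = make_background_table()
    ages = np.arange(background.max_age + 1, dtype=float)
    tables: dict[str, RateTable] = {}
    totals = {sex: np.zeros_like(ages) for sex in ("male", "female")}
    for site in RISK_SITES:
        if site not in shapes:
            raise ValueError(f"no shape for risk site {site!r}")
        rates = {}
        for sex in ("male", "female"):
            lam = np.asarray(shapes[site][sex].rate(ages), dtype=float)
            rates[sex] = lam
            totals[sex] += lam
        tables[site] = RateTable(rates=rates, site=site)
    for sex in ("male", "female"):
        bg = background.rates[sex]
        bad = np.nonzero(totals[sex] >= bg)[0]
        if bad.size:
            raise ValueError(
                f"summed cancer mortality reaches all-cause mortality at age "
                f"{int(bad[0])} ({sex})"
            )
    return tables


def make_toy_worked_example() -> dict:
    """A hand-checkable three-site bundle with closed-form golden values.

    The toy is built so every ERR modifier is inert: three solid sites with
    ``gamma = eta = 0`` (and zero-beta rows for the remaining sites), two
    exposures at ages 30 and 40 (so ``e* = 0``), a flat background hazard
    of 0.1/yr, flat site rates, DDREF 1, no latency, and a three-year life
    table starting at age 60.  The radiation excess rate is then the
    age-independent constant

        ``M = sum_site lambda_site * beta_site * d_site``

    summed over both exposures, and with total hazard ``mu = 0.1 + M`` the
    life-table quantities have closed forms frozen into ``golden``:
    ``REID = (M / mu) * (1 - exp(-3 mu))`` and
    ``LE = (1 - exp(-3 mu)) / mu`` (trapezoid-corrected per interval).

    Returns a dict with the parameter set, rate tables, exposure history,
    patient, disease hazard and the ``golden`` values.
    """
    from .mortality import RateTable as RT  # local alias for clarity

    beta = {"stomach": 0.5, "colon": 0.3, "lung": 0.2}
    solid = {
        site: SolidSiteParams(
            beta_male=beta.get(site, 0.0),
            beta_female=beta.get(site, 0.0),
            gamma=0.0,
            eta=0.0,
        )
        for site in SOLID_SITES
    }
    params = ERRParameterSet(
        solid=solid,
        leukemia=LeukemiaParams(0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    )

    max_age = 63
    flat = {
        "male": np.full(max_age + 1, 0.1),
        "female": np.full(max_age + 1, 0.1),
    }
    background = RT(rates=flat)
    lam = {"stomach": 0.02, "colon": 0.01, "lung": 0.005}
    cancer = {
        site: RT(
            rates={
                "male": np.full(max_age + 1, lam.get(site, 0.0)),
                "female": np.full(max_age + 1, lam.get(site, 0.0)),
            },
            site=site,
        )
        for site in RISK_SITES
    }

    dose_mSv = {"stomach": 100.0, "colon": 200.0, "lung": 50.0}
    organ_doses = {o: dose_mSv.get(o, 0.0) for o in ORGANS}
    vec = OrganDoseVector(organ_doses=organ_doses, effective_dose_mSv=10.0)
    history: ExposureHistory = (
        ExposureEvent(30.0, vec),
        ExposureEvent(40.0, vec),
    )

    # per-event excess rate: sum lam_s * beta_s * d_s(Gy); two events double it
    m_one = sum(lam[s] * beta[s] * dose_mSv[s] / 1000.0 for s in beta)
    m_rad = 2.0 * m_one
    mu = 0.1 + m_rad
    q = 1.0 - np.exp(-mu)
    # three annual intervals starting at age 60
    l_end = float(np.exp(-3.0 * mu))
    reid = (m_rad / mu) * (1.0 - l_end)
    le = float(sum(np.exp(-mu * k) * (1.0 - q / 2.0) for k in range(3)))

    disease = DiseaseHazard(rate_per_year=0.02, cure_after_years=3.0)
    mu_d = mu + disease.rate_per_year
    reid_with_disease = (m_rad / mu_d) * (1.0 - float(np.exp(-3.0 * mu_d)))

    return {
        "err_params": params,
        "background": background,
        "cancer_tables": cancer,
        "history": history,
        "start_age": 60.0,
        "max_age": max_age,
        "disease_hazard": disease,
        "risk_config": RiskConfig(
            ddref=1.0, latency_solid_years=0.0, latency_leukemia_years=0.0
        ),
        "golden": {
            "m_rad": m_rad,
            "reid": reid,
            "life_expectancy_years": le,
            "reid_with_disease": reid_with_disease,
        },
    }


def write_synthetic_inputs(out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write background.csv and cancer_rates.csv in the loaders' CSV dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    background = make_background_table(seed=seed)
    cancer = make_cancer_rate_tables(background=background)
    ages = np.arange(background.max_age + 1)
    rows = [
        {"age": int(a), "sex": sex, "rate": background.rates[sex][a]}
        for sex in ("male", "female")
        for a in ages
    ]
    bg_path = out / "background.csv"
    pd.DataFrame(rows).to_csv(bg_path, index=False)
    crows = [
        {"age": int(a), "sex": sex, "site": site, "rate": tbl.rates[sex][a]}
        for site, tbl in cancer.items()
        for sex in ("male", "female")
        for a in ages
    ]
    ca_path = out / "cancer_rates.csv"
    pd.DataFrame(crows).to_csv(ca_path, index=False)
    meta = {"seed": seed}
    meta_path = out / "metadata.yaml"
    import yaml

    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    return {"background": bg_path, "cancer_rates": ca_path, "metadata": meta_path}
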