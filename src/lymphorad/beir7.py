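"""Excess-relative-risk models for radiation-induced cancer mortality.

Implements the BEIR VII committee's preferred ERR models, with risk
transported multiplicatively onto baseline (naturally occurring) cancer
mortality rates:

* solid-cancer sites::

      ERR(d, s, e, a) = beta_s(sex) * d * exp(gamma * e*) * (a / 60) ** eta

* leukaemia (linear-quadratic in dose, time-since-exposure modified)::

      ERR = beta(sex) * d * (1 + theta * d)
            * exp(gamma * e* + delta * ln(t/25) + phi * e* * ln(t/25))

where ``d`` is absorbed organ dose in Gy, ``e`` the age at exposure,
``a`` the attained age, ``t = a - e``, and ``e* = (e - 30)/10`` for
exposures before age 30 and 0 afterwards.

Multiple exposures combine additively on the ERR scale.  Solid-cancer ERR is
divided by a dose and dose-rate effectiveness factor (DDREF, default 1.5);
the leukaemia model carries its curvature explicitly and receives none.
A minimum latency suppresses risk immediately after exposure (defaults:
5 y solid, 2 y leukaemia).

Parameters ship as package data (``data/err_solid.csv`` and
``data/err_leukemia.csv``) and can be overridden by user files of the same
shape.  The thyroid row applies incidence-model coefficients to the baseline
thyroid-cancer mortality rate — the committee fit no thyroid mortality
model — which slightly overstates that (very small) term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .dosimetry import ORGANS
from .schedule import ExposureHistory

__all__ = [
    "SOLID_SITES",
    "SITE_TO_ORGAN",
    "FEMALE_ONLY_SITES",
    "MALE_ONLY_SITES",
    "SolidSiteParams",
    "LeukemiaParams",
    "ERRParameterSet",
    "RiskConfig",
    "load_err_parameters",
    "age_at_exposure_transform",
    "err_solid",
    "err_leukemia",
    "excess_mortality_rate",
]

#: Solid-cancer sites with ERR parameters, in table order.
SOLID_SITES: tuple[str, ...] = (
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

#: Dose site feeding each risk site; leukaemia uses the bone-marrow dose.
SITE_TO_ORGAN: Mapping[str, str] = {s: s for s in SOLID_SITES} | {"leukemia": "bone_marrow"}

FEMALE_ONLY_SITES = frozenset({"breast", "uterus", "ovary"})
MALE_ONLY_SITES = frozenset({"prostate"})


@dataclass(frozen=True)
class SolidSiteParams:
    beta_male: float  # ERR per Gy at e>=30, a=60
    beta_female: float
    gamma: float  # per decade of e*
    eta: float  # exponent of attained age / 60

    def beta(self, sex: str) -> float:
        return self.beta_male if sex == "male" else self.beta_female


@dataclass(frozen=True)
class LeukemiaParams:
    beta_male: float
    beta_female: float
    theta: float  # dose-curvature, per Gy
    gamma: float
    delta: float
    phi: float

    def beta(self, sex: str) -> float:
        return self.beta_male if sex == "male" else self.beta_female


@dataclass(frozen=True)
class ERRParameterSet:
    solid: Mapping[str, SolidSiteParams]
    leukemia: LeukemiaParams

    def __post_init__(self) -> None:
        for site in self.solid:
            organ = SITE_TO_ORGAN.get(site)
            if organ is None or organ not in ORGANS:
                raise ValueError(f"site {site!r} has no matching organ dose row")


@dataclass(frozen=True)
class RiskConfig:
    """Modelling constants left open by the risk-transport literature."""

    ddref: float = 1.5
    latency_solid_years: float = 5.0
    latency_leukemia_years: float = 2.0

    def __post_init__(self) -> None:
        if self.ddref < 1:
            raise ValueError("ddref must be >= 1")
        if self.latency_solid_years < 0 or self.latency_leukemia_years < 0:
            raise ValueError("latencies must be non-negative")


def load_err_parameters(
    solid_csv: str | Path | None = None, leukemia_csv: str | Path | None = None
) -> ERRParameterSet:
    """Load ERR fit parameters from CSV (bundled defaults when paths omitted)."""
    data = resources.files("lymphorad.data")
    sdf = pd.read_csv(solid_csv if solid_csv else str(data / "err_solid.csv"))
    ldf = pd.read_csv(leukemia_csv if leukemia_csv else str(data / "err_leukemia.csv"))
    solid = {
        str(r.site): SolidSiteParams(
            beta_male=float(r.beta_male),
            beta_female=float(r.beta_female),
            gamma=float(r.gamma),
            eta=float(r.eta),
        )
        for r in sdf.itertuples()
    }
    lrow = ldf.iloc[0]
    leuk = LeukemiaParams(
        beta_male=float(lrow.beta_male),
        beta_female=float(lrow.beta_female),
        theta=float(lrow.theta),
        gamma=float(lrow.gamma),
        delta=float(lrow.delta),
        phi=float(lrow.phi),
    )
    return ERRParameterSet(solid=solid, leukemia=leuk)


def age_at_exposure_transform(e: float) -> float:
    """``e* = (e - 30)/10`` for exposure ages below 30, else 0."""
    if e < 0:
        raise ValueError("age at exposure must be non-negative")
    return (e - 30.0) / 10.0 if e < 30.0 else 0.0


def err_solid(
    site: str,
    d_gray: float,
    sex: str,
    e: float,
    a: float,
    params: ERRParameterSet,
    latency_years: float = 0.0,
) -> float:
    """Solid-cancer mortality ERR for one exposure (no DDREF applied here)."""
    if a <= e:
        raise ValueError("attained age must exceed age at exposure")
    if d_gray < 0:
        raise ValueError("dose must be non-negative")
    if d_gray == 0.0 or (a - e) < latency_years:
        return 0.0
    p = params.solid[site]
    e_star = age_at_exposure_transform(e)
    return p.beta(sex) * d_gray * math.exp(p.gamma * e_star) * (a / 60.0) ** p.eta


def err_leukemia(
    d_gray: float,
    sex: str,
    e: float,
    a: float,
    params: ERRParameterSet,
    latency_years: float = 0.0,
) -> float:
    """Leukaemia mortality ERR for one exposure (linear-quadratic in dose)."""
    if a <= e:
        raise ValueError("attained age must exceed age at exposure")
    if d_gray < 0:
        raise ValueError("dose must be non-negative")
    t = a - e
    if d_gray == 0.0 or t < latency_years:
        return 0.0
    p = params.leukemia
    e_star = age_at_exposure_transform(e)
    log_t = math.log(t / 25.0)
    return (
        p.beta(sex)
        * d_gray
        * (1.0 + p.theta * d_gray)
        * math.exp(p.gamma * e_star + p.delta * log_t + p.phi * e_star * log_t)
    )


def _site_active(site: str, sex: str) -> bool:
    if site in FEMALE_ONLY_SITES:
        return sex == "female"
    if site in MALE_ONLY_SITES:
        return sex == "male"
    return True


def excess_mortality_rate(
    a: float,
    sex: str,
    history: ExposureHistory,
    baseline_rates: Mapping[str, float],
    params: ERRParameterSet,
    config: RiskConfig = RiskConfig(),
) -> float:
    """Radiation-induced excess mortality rate (per person-year) at attained age ``a``.

    ``baseline_rates`` maps every risk site (the solid sites plus
    ``"leukemia"``) to its baseline cancer mortality rate at ``(a, sex)``.
    Organ doses are read from each exposure event; tabulated mSv equivalent
    doses are treated as mGy absorbed dose (photon radiation, weighting
    factor 1) and converted to Gy.  Exposures at or after ``a`` contribute
    nothing; contributions are additive on the ERR scale, with solid-site
    sums divided by the DDREF.
    """
    sites = list(params.solid) + ["leukemia"]
    missing = [s for s in sites if _site_active(s, sex) and s not in baseline_rates]
    if missing:
        raise ValueError(f"baseline cancer mortality missing for sites: {missing}")
    total = 0.0
    for site in sites:
        if not _site_active(site, sex):
            continue
        organ = SITE_TO_ORGAN[site]
        err_sum = 0.0
        for event in history:
            e = event.age_at_exposure_years
            if a <= e:
                continue
            d_gray = event.organ_doses.organ_doses[organ] / 1000.0  # mGy -> Gy
            if site == "leukemia":
                err_sum += err_leukemia(
                    d_gray, sex, e, a, params, config.latency_leukemia_years
                )
            else:
                err_sum += err_solid(
                    site, d_gray, sex, e, a, params, config.latency_solid_years
                )
        if site != "leukemia":
            err_sum /= config.ddref
        total += baseline_rates[site] * err_sum
    return total
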