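"""USEPA-style dietary exposure and risk arithmetic.

Non-carcinogenic route: average daily intake
``ADI = C x IR x EF x ED / (BW x AT)`` (mg/kg body weight/day), target
hazard quotient ``THQ = ADI / RfD``, hazard index ``HI = sum of THQ`` over
contaminants; concern when THQ or HI exceeds 1.  Carcinogenic route (Cd
only): lifetime risk ``R = SF x ADI``, banded at 1e-6 (negligible below)
and 1e-4 (unacceptable above).

Under the default averaging-time rule ``ed_times_365`` (AT = ED x 365
days, EF = 365 d/a) the exposure factor EF x ED / AT collapses to 1 and
ADI reduces to C x IR / BW; the USEPA carcinogenic convention of a fixed
70-year averaging time is available as ``at_rule="lifetime_70y"``.

All quantities are linear in concentration, so risk evaluated at the crop
mean equals the mean of per-sample risks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import EmptyGroupError, ParameterError
from .io_config import (
    ParameterSet,
    PopulationParams,
    SampleRecord,
    subset,
)

R_NEGLIGIBLE_CUT = 1e-6
R_UNACCEPTABLE_CUT = 1e-4


@dataclass(frozen=True)
class RiskResult:
    """Risk indicators for one sample (or one crop mean) and population."""

    crop: str
    population: str
    adi: Mapping[str, float]
    thq: Mapping[str, float]
    hi: float
    r_cd: float
    r_band: str
    hi_flag: bool
    sample_id: str | None = None


def exposure_factor(pop: PopulationParams, at_rule: str) -> float:
    """EF x ED / AT (1/days scaled to dimensionless daily averaging)."""
    if at_rule == "ed_times_365":
        at_days = pop.ed_years * 365.0
    elif at_rule == "lifetime_70y":
        at_days = 70.0 * 365.0
    else:
        raise ParameterError(f"unknown at_rule {at_rule!r}")
    return pop.ef_dpera * pop.ed_years / at_days


def compute_adi(c: float, pop: PopulationParams, crop: str,
                at_rule: str = "ed_times_365") -> float:
    """Average daily intake, mg per kg body weight per day."""
    if c < 0:
        raise ParameterError(f"concentration must be non-negative, got {c}")
    ir = pop.ir_for(crop)
    return c * ir * exposure_factor(pop, at_rule) / pop.bw_kg


def compute_thq(adi: float, rfd: float) -> float:
    """Target hazard quotient ADI/RfD."""
    if rfd <= 0:
        raise ParameterError(f"reference dose must be positive, got {rfd}")
    return adi / rfd


def compute_hi(thqs: Mapping[str, float]) -> float:
    """Hazard index: sum of per-element THQs."""
    if not thqs:
        raise EmptyGroupError("hazard index needs at least one THQ")
    return float(sum(thqs.values()))


def compute_r(adi_cd: float, sf: float | None) -> float:
    """Lifetime carcinogenic risk SF x ADI."""
    if sf is None or sf <= 0:
        raise ParameterError(
            "carcinogenic risk requires a positive slope factor "
            "(defined for Cd only)"
        )
    return sf * adi_cd


def classify_r(r: float) -> str:
    """Band a carcinogenic risk: negligible / cautionary / unacceptable."""
    if r < 0:
        raise ParameterError(f"risk must be non-negative, got {r}")
    if r < R_NEGLIGIBLE_CUT:
        return "negligible"
    if r <= R_UNACCEPTABLE_CUT:
        return "cautionary"
    return "unacceptable"


def risk_from_concentrations(conc: Mapping[str, float], crop: str,
                             params: ParameterSet, population: str,
                             sample_id: str | None = None) -> RiskResult:
    """Full risk computation from a concentration map (element -> mg/kg)."""
    pop = params.population(population)
    adi = {el: compute_adi(c, pop, crop, params.at_rule) for el, c in conc.items()}
    thq = {el: compute_thq(adi[el], params.element(el).rfd_mgkgday) for el in adi}
    hi = compute_hi(thq)
    if "Cd" not in adi:
        raise ParameterError("carcinogenic risk requires a Cd concentration")
    r_cd = compute_r(adi["Cd"], params.element("Cd").sf_permgkgday)
    return RiskResult(
        crop=crop,
        population=population,
        adi=adi,
        thq=thq,
        hi=hi,
        r_cd=r_cd,
        r_band=classify_r(r_cd),
        hi_flag=hi > 1.0,
        sample_id=sample_id,
    )


def per_sample_risk(records: Iterable[SampleRecord], params: ParameterSet,
                    population: str) -> list[RiskResult]:
    """One RiskResult per record, using that record's own concentrations."""
    return [
        risk_from_concentrations(
            {"F": r.f_mgkg, "Cd": r.cd_mgkg}, r.crop, params, population,
            sample_id=r.sample_id,
        )
        for r in records
    ]


def mean_risk(records: Sequence[SampleRecord], crop: str, params: ParameterSet,
              population: str) -> RiskResult:
    """Risk evaluated at the crop's mean concentrations.

    Equals the element-wise mean of per-sample results by linearity.
    """
    group = subset(records, crop)
    if not group:
        raise EmptyGroupError(f"no records for crop {crop!r}")
    n = len(group)
    conc = {
        "F": sum(r.f_mgkg for r in group) / n,
        "Cd": sum(r.cd_mgkg for r in group) / n,
    }
    return risk_from_concentrations(conc, crop, params, population)
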