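"""Upgrade scenarios: IPHS-compliant secondary hospital, medical college.

Two budget-impact scenarios adjust the three payment streams of a hospital:

* **IPHS upgrade** — staffing is brought up to the Indian Public Health
  Standards norms (the shortfall priced at current salaries), capital
  upgrade is financed at an annual fraction (one-fifth) of the existing
  capital stock, and the volume-driven inpatient stream is recomputed at an
  uplifted bed capacity. The indirect stream is unchanged.
* **Medical-college upgrade** — the hospital moves to tertiary pricing: a
  tertiary outpatient risk-adjustment model, tertiary case tariffs, and the
  tertiary per-bed indirect rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .indirect import IndirectRateConfig, indirect_budget
from .inpatient import (
    SpecialtyCostTable,
    SpecialtyProfile,
    TariffTable,
    default_specialty_costs,
    default_specialty_profiles,
    default_tariff_table,
    inpatient_budget,
)
from .outpatient import RiskAdjustmentModel, canonical_model, predict_outpatient_budget
from .types import CADRES, HospitalPayout, HospitalRecord

__all__ = [
    "StaffingNorms",
    "SalarySchedule",
    "ScenarioConfig",
    "staffing_shortfall_cost",
    "capital_gap_annualization",
    "apply_iphs",
    "apply_medical_college",
    "default_staffing_norms",
    "default_salary_schedule",
    "placeholder_tertiary_model",
    "read_norms_csv",
    "read_salaries_csv",
    "IPHS_BED_UPLIFT_PRESET",
]

#: Bed-capacity uplift consistent with the roughly 2.3-fold rise in mean
#: inpatient payout when secondary hospitals are brought to IPHS standards.
IPHS_BED_UPLIFT_PRESET = 2.3

#: Tertiary-to-secondary case tariff ratio consistent with a 123% rise in
#: the mean inpatient payout under the medical-college upgrade.
TERTIARY_TARIFF_MULTIPLIER_PRESET = 2.23


@dataclass(frozen=True)
class StaffingNorms:
    """Staffing requirement as a step function of bed capacity.

    ``steps`` is a sequence of (min_beds, {cadre: headcount}); the
    requirement at a given bed size is the entry with the largest
    ``min_beds`` not exceeding it. Headcounts must be non-decreasing in
    beds for every cadre.
    """

    steps: tuple[tuple[int, dict[str, float]], ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.steps, key=lambda s: s[0])
        object.__setattr__(self, "steps", tuple(ordered))
        prev: dict[str, float] = {}
        for _, req in ordered:
            if any(v < 0 for v in req.values()):
                raise ValueError("required headcounts must be >= 0")
            for cadre, v in req.items():
                if v < prev.get(cadre, 0.0):
                    raise ValueError(
                        f"norm for {cadre!r} must be non-decreasing in beds"
                    )
            prev = {**prev, **req}

    def required(self, beds: int) -> dict[str, float]:
        """Headcount requirement at a given bed size."""
        current: dict[str, float] = {}
        for min_beds, req in self.steps:
            if beds >= min_beds:
                current = req
        return dict(current)


@dataclass(frozen=True)
class SalarySchedule:
    """Annual salary (INR/year) per staffing cadre."""

    annual_salary: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.annual_salary.values()):
            raise ValueError("salaries must be > 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the upgrade scenarios.

    ``capital_annual_fraction`` is the share of the existing capital stock
    financed per year for the IPHS capital upgrade (default one-fifth);
    ``iphs_bed_uplift`` the multiplicative bed-capacity factor of the IPHS
    scenario; ``op_shortfall_split`` the fraction of the staffing-shortfall
    (and capital) cost attributed to the outpatient stream, the remainder
    going to inpatient. Tertiary inputs default to clearly-labelled
    synthetic placeholders unless supplied.
    """

    capital_annual_fraction: float = 0.20
    iphs_bed_uplift: float = 1.0
    op_shortfall_split: float = 1.0
    tertiary_model: RiskAdjustmentModel | None = None
    tertiary_tariffs: TariffTable | None = None
    tertiary_nonpmjay_costs: SpecialtyCostTable | None = None
    tertiary_tariff_multiplier: float = TERTIARY_TARIFF_MULTIPLIER_PRESET
    indirect_rates: IndirectRateConfig = field(default_factory=IndirectRateConfig)
    secondary_model: RiskAdjustmentModel = field(default_factory=canonical_model)
    tariffs: TariffTable = field(default_factory=default_tariff_table)
    nonpmjay_costs: SpecialtyCostTable = field(default_factory=default_specialty_costs)
    allow_placeholders: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.capital_annual_fraction <= 1.0:
            raise ValueError("capital_annual_fraction must lie in (0, 1]")
        if self.iphs_bed_uplift < 1.0:
            raise ValueError("iphs_bed_uplift must be >= 1")
        if not 0.0 <= self.op_shortfall_split <= 1.0:
            raise ValueError("op_shortfall_split must lie in [0, 1]")
        if self.tertiary_tariff_multiplier <= 0:
            raise ValueError("tertiary_tariff_multiplier must be > 0")


def staffing_shortfall_cost(
    current: Mapping[str, float],
    norms: StaffingNorms,
    beds: int,
    salaries: SalarySchedule,
) -> float:
    """Annual cost of filling staffing gaps against the norms.

    Σ_cadre max(0, required − current) × salary. Surpluses in one cadre do
    not offset shortfalls in another.
    """
    required = norms.required(beds)
    total = 0.0
    for cadre, req in required.items():
        gap = max(0.0, req - float(current.get(cadre, 0.0)))
        if gap > 0:
            if cadre not in salaries.annual_salary:
                raise KeyError(f"no salary for cadre {cadre!r}")
            total += gap * salaries.annual_salary[cadre]
    return total


def capital_gap_annualization(existing_capital: float, fraction: float = 0.20) -> float:
    """Annualised capital upgrade outlay: existing capital × fraction."""
    if existing_capital < 0:
        raise ValueError("existing_capital must be >= 0")
    return existing_capital * fraction


def apply_iphs(
    hospital: HospitalRecord,
    base_payout: HospitalPayout,
    norms: StaffingNorms,
    salaries: SalarySchedule,
    config: ScenarioConfig,
    profiles: Sequence[SpecialtyProfile] | None = None,
) -> HospitalPayout:
    """Payout after upgrading a hospital to the IPHS staffing/capital norms.

    The staffing-shortfall and annualised-capital costs are split between
    the outpatient and inpatient streams by ``config.op_shortfall_split``
    (default: all outpatient); the inpatient stream is recomputed at
    ``beds × iphs_bed_uplift`` since drug/consumable growth is volume
    driven; the indirect stream is unchanged.
    """
    shortfall = staffing_shortfall_cost(hospital.staffing, norms, hospital.beds, salaries)
    capital = capital_gap_annualization(
        hospital.capital_cost, config.capital_annual_fraction
    )
    extra = shortfall + capital
    if profiles is None:
        profiles = default_specialty_profiles(hospital.specialty_bed_shares)
    uplifted_beds = hospital.beds * config.iphs_bed_uplift
    inpatient = inpatient_budget(
        uplifted_beds, profiles, config.tariffs, config.nonpmjay_costs
    )
    return HospitalPayout(
        hospital_id=hospital.hospital_id,
        scenario="iphs",
        outpatient=base_payout.outpatient + extra * config.op_shortfall_split,
        inpatient=inpatient + extra * (1.0 - config.op_shortfall_split),
        indirect=base_payout.indirect,
        provenance=base_payout.provenance,
    )


def placeholder_tertiary_model() -> RiskAdjustmentModel:
    """Synthetic stand-in for the tertiary outpatient regression.

    The tertiary coefficient set is not redistributable; this placeholder
    scales every secondary coefficient by a common factor so the tertiary
    outpatient budget exceeds the secondary one by a modest margin, which
    is what the three printed scenario uplifts (total +91.5%, inpatient
    +123%, indirect +79.6%) jointly imply for the outpatient stream.
    Outputs computed with it carry a provenance flag.
    """
    sec = canonical_model()
    f = 1.06
    return replace(
        sec,
        intercept=sec.intercept * f,
        tier2_offset=sec.tier2_offset * f,
        tier3_offset=sec.tier3_offset * f,
        beta_population=sec.beta_population * f,
        beta_beds=sec.beta_beds * f,
        beta_imr=sec.beta_imr * f,
        beta_age=sec.beta_age * f,
        beta_util=sec.beta_util * f,
        r2=float("nan"),
        adj_r2=float("nan"),
    )


def apply_medical_college(
    hospital: HospitalRecord,
    config: ScenarioConfig,
    profiles: Sequence[SpecialtyProfile] | None = None,
) -> HospitalPayout:
    """Payout after upgrading a hospital to a medical college (tertiary care).

    Outpatient comes from the tertiary risk-adjustment model, inpatient from
    tertiary case tariffs (explicit tables, or the secondary tables scaled by
    ``tertiary_tariff_multiplier``), indirect from the tertiary per-bed rate.
    """
    provenance: list[str] = []
    model = config.tertiary_model
    if model is None:
        if not config.allow_placeholders:
            raise ValueError(
                "tertiary model not supplied and placeholders are disabled"
            )
        model = placeholder_tertiary_model()
        provenance.append("placeholder-tertiary-model")

    tariffs = config.tertiary_tariffs
    nonpmjay = config.tertiary_nonpmjay_costs
    if tariffs is None or nonpmjay is None:
        if not config.allow_placeholders:
            raise ValueError(
                "tertiary tariffs not supplied and placeholders are disabled"
            )
        if tariffs is None:
            tariffs = config.tariffs.scaled(config.tertiary_tariff_multiplier)
        if nonpmjay is None:
            nonpmjay = config.nonpmjay_costs.scaled(config.tertiary_tariff_multiplier)
        provenance.append("scaled-secondary-tariffs")

    if profiles is None:
        profiles = default_specialty_profiles(hospital.specialty_bed_shares)

    outpatient = predict_outpatient_budget(model, hospital.district, hospital.beds)
    inpatient = inpatient_budget(hospital.beds, profiles, tariffs, nonpmjay)
    indirect = indirect_budget(hospital.beds, config.indirect_rates.rate_medical_college)
    return HospitalPayout(
        hospital_id=hospital.hospital_id,
        scenario="medical-college",
        outpatient=outpatient,
        inpatient=inpatient,
        indirect=indirect,
        provenance=tuple(provenance),
    )


# -- defaults and IO ---------------------------------------------------------

def default_staffing_norms() -> StaffingNorms:
    """IPHS-like staffing requirement steps by bed capacity (overridable)."""
    return StaffingNorms(
        steps=(
            (0, {"doctor": 25, "paramedical": 80, "support": 50}),
            (100, {"doctor": 35, "paramedical": 110, "support": 70}),
            (200, {"doctor": 55, "paramedical": 170, "support": 110}),
            (300, {"doctor": 75, "paramedical": 230, "support": 150}),
            (400, {"doctor": 95, "paramedical": 290, "support": 190}),
            (500, {"doctor": 115, "paramedical": 350, "support": 230}),
        )
    )


def default_salary_schedule() -> SalarySchedule:
    """Default annual salaries (INR/year) per cadre."""
    return SalarySchedule(
        annual_salary={"doctor": 1_200_000.0, "paramedical": 400_000.0, "support": 250_000.0}
    )


def read_norms_csv(path) -> StaffingNorms:
    """Read staffing norms (columns: min_beds, then one column per cadre)."""
    df = pd.read_csv(path)
    steps = []
    for _, row in df.iterrows():
        req = {c: float(row[c]) for c in CADRES if c in df.columns}
        steps.append((int(row["min_beds"]), req))
    return StaffingNorms(steps=tuple(steps))


def read_salaries_csv(path) -> SalarySchedule:
    """Read a salary schedule (columns: cadre, annual_salary_inr)."""
    df = pd.read_csv(path)
    return SalarySchedule(
        annual_salary=dict(zip(df["cadre"], df["annual_salary_inr"].astype(float)))
    )
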