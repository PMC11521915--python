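"""Case-based bundled payment for inpatient care.

The inpatient stream pays a hospital per expected admission. Expected
annual admissions in a specialty follow from bed capacity:

    admissions = beds × bed_share × BOR × 365 / ALOS

(BOR = bed occupancy rate, ALOS = average length of stay in days).
Admissions split into cases covered by the national insurance scheme's
health benefit packages (HBPs), priced through a tariff table with a
case-mix, and the remainder, priced at specialty-level weighted average
costs per admission.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .types import SPECIALTIES

__all__ = [
    "SpecialtyProfile",
    "TariffTable",
    "SpecialtyCostTable",
    "expected_admissions",
    "weighted_specialty_cost",
    "inpatient_budget",
    "default_specialty_costs",
    "default_specialty_profiles",
    "default_tariff_table",
    "economic_cost",
    "read_specialty_costs_csv",
    "read_tariff_csv",
]

#: Fraction of the capital stock charged annually under the economic-cost
#: convention (full recurrent cost plus one-fifth of capital).
CAPITAL_ANNUAL_FRACTION = 0.20


@dataclass(frozen=True)
class SpecialtyProfile:
    """Admission-generating profile of one specialty.

    ``bed_share`` is the specialty's fraction of inpatient beds; ``alos``
    the average length of stay in days; ``bor`` the bed occupancy rate;
    ``pmjay_share`` the fraction of admissions covered by insurance HBPs.
    """

    specialty: str
    bed_share: float
    alos: float
    bor: float
    pmjay_share: float

    def __post_init__(self) -> None:
        if self.specialty not in SPECIALTIES:
            raise ValueError(f"unknown specialty {self.specialty!r}")
        for name in ("bed_share", "bor", "pmjay_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.alos > 0:
            raise ValueError(f"alos must be > 0, got {self.alos}")


@dataclass(frozen=True)
class TariffTable:
    """HBP tariff list with an annual case-mix.

    ``entries`` maps HBP code to (specialty, cost per case in INR);
    ``case_mix`` maps HBP code to its share of the specialty's annual HBP
    caseload (shares sum to one within each specialty).
    """

    entries: Mapping[str, tuple[str, float]]
    case_mix: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(cost <= 0 for _, cost in self.entries.values()):
            raise ValueError("tariff costs must be > 0")
        by_spec: dict[str, float] = {}
        for code, share in self.case_mix.items():
            if code not in self.entries:
                raise ValueError(f"case-mix code {code!r} missing from tariff entries")
            spec = self.entries[code][0]
            by_spec[spec] = by_spec.get(spec, 0.0) + share
        for spec, total in by_spec.items():
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"case-mix shares for {spec!r} sum to {total}, expected 1"
                )

    def specialties(self) -> set[str]:
        return {spec for spec, _ in self.entries.values()}

    def mean_cost(self, specialty: str) -> float:
        """Case-mix-weighted mean HBP cost per admission in a specialty."""
        total = 0.0
        weight = 0.0
        for code, (spec, cost) in self.entries.items():
            if spec == specialty:
                share = self.case_mix.get(code, 0.0)
                total += share * cost
                weight += share
        if weight == 0.0:
            raise KeyError(f"no tariff entries for specialty {specialty!r}")
        return total / weight

    def scaled(self, factor: float) -> "TariffTable":
        """New table with every tariff multiplied by ``factor``."""
        return TariffTable(
            entries={c: (s, cost * factor) for c, (s, cost) in self.entries.items()},
            case_mix=dict(self.case_mix),
        )


@dataclass(frozen=True)
class SpecialtyCostTable:
    """Weighted average cost per admission for non-HBP cases, by specialty."""

    cost_per_admission: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cost_per_admission.values()):
            raise ValueError("specialty costs must be > 0")

    def scaled(self, factor: float) -> "SpecialtyCostTable":
        return SpecialtyCostTable(
            {s: c * factor for s, c in self.cost_per_admission.items()}
        )


def expected_admissions(beds: int, profile: SpecialtyProfile) -> float:
    """Expected annual admissions in one specialty from bed capacity.

    beds × bed_share × BOR × 365 / ALOS, kept real-valued: rounding to
    whole admissions would introduce order-dependent bias and is left to
    the report layer.
    """
    if beds < 0:
        raise ValueError(f"beds must be >= 0, got {beds}")
    return beds * profile.bed_share * profile.bor * 365.0 / profile.alos


def weighted_specialty_cost(
    cases: Mapping[str, float], costs: SpecialtyCostTable
) -> float:
    """Case-weighted average cost per admission, Σ nᵢcᵢ / Σ nᵢ."""
    if any(n < 0 for n in cases.values()):
        raise ValueError("case counts must be >= 0")
    total_cases = sum(cases.values())
    if total_cases <= 0:
        raise ValueError("at least one positive case count required")
    return (
        sum(n * costs.cost_per_admission[s] for s, n in cases.items()) / total_cases
    )


def inpatient_budget(
    beds: int,
    profiles: Sequence[SpecialtyProfile],
    tariffs: TariffTable,
    nonpmjay_costs: SpecialtyCostTable,
) -> float:
    """Annual case-based inpatient budget (INR/year) for one hospital.

    Per specialty, expected admissions split into an HBP-covered portion
    (priced through the tariff case-mix) and the remainder (priced at the
    specialty's non-HBP weighted cost); the budget is the sum over
    specialties and therefore additive and linear in beds.
    """
    share_sum = sum(p.bed_share for p in profiles)
    if abs(share_sum - 1.0) > 1e-6:
        raise ValueError(f"profile bed shares must sum to 1, got {share_sum}")
    if beds == 0:
        return 0.0
    tariff_specs = tariffs.specialties()
    total = 0.0
    for p in profiles:
        adm = expected_admissions(beds, p)
        pmjay_cases = adm * p.pmjay_share
        other_cases = adm - pmjay_cases
        if pmjay_cases > 0 and p.specialty not in tariff_specs:
            raise KeyError(f"specialty {p.specialty!r} missing from tariff table")
        if other_cases > 0 and p.specialty not in nonpmjay_costs.cost_per_admission:
            raise KeyError(
                f"specialty {p.specialty!r} missing from non-HBP cost table"
            )
        if pmjay_cases > 0:
            total += pmjay_cases * tariffs.mean_cost(p.specialty)
        if other_cases > 0:
            total += other_cases * nonpmjay_costs.cost_per_admission[p.specialty]
    return total


def economic_cost(
    recurrent: float, capital: float, capital_fraction: float = CAPITAL_ANNUAL_FRACTION
) -> float:
    """Annual economic cost: full recurrent cost plus a fraction of capital.

    Used when building tariffs from raw cost components; packaged tariff
    values already embed this convention.
    """
    if recurrent < 0 or capital < 0:
        raise ValueError("cost components must be >= 0")
    return recurrent + capital_fraction * capital


# -- defaults and IO ---------------------------------------------------------

def default_specialty_costs() -> SpecialtyCostTable:
    """The packaged specialty-wise weighted costs for non-HBP admissions."""
    with resources.files("hospfin.data").joinpath("specialty_costs.csv").open() as fh:
        df = pd.read_csv(fh)
    return SpecialtyCostTable(
        dict(zip(df["specialty"], df["cost_per_admission_inr"].astype(float)))
    )


# Facility-level admission profile emulating the costing study's observed
# bed distribution, stay lengths and insurance coverage (the study's own
# values are not published facility-by-facility; these are overridable).
_DEFAULT_PROFILE_PARAMS = {
    # specialty: (bed_share, alos_days, bor, pmjay_share)
    "Paediatrics": (0.12, 3.5, 0.80, 0.40),
    "General Medicine": (0.25, 4.0, 0.85, 0.35),
    "Obstetrics and gynaecology": (0.18, 3.0, 0.85, 0.50),
    "Ear Nose and Throat": (0.06, 2.5, 0.70, 0.40),
    "General Surgery": (0.15, 5.0, 0.80, 0.45),
    "Ophthalmology": (0.06, 2.0, 0.70, 0.45),
    "Orthopedics": (0.18, 6.0, 0.80, 0.45),
}


def default_specialty_profiles(
    bed_shares: Mapping[str, float] | None = None,
) -> list[SpecialtyProfile]:
    """Default admission profiles; bed shares overridable per hospital."""
    profiles = []
    for spec, (share, alos, bor, pmjay) in _DEFAULT_PROFILE_PARAMS.items():
        if bed_shares is not None:
            share = bed_shares[spec]
        profiles.append(
            SpecialtyProfile(
                specialty=spec, bed_share=share, alos=alos, bor=bor, pmjay_share=pmjay
            )
        )
    return profiles


def default_tariff_table() -> TariffTable:
    """A synthetic HBP tariff table.

    The actual insurance tariff list is not redistributable, so the default
    ships two representative packages per specialty whose case-mix-weighted
    mean sits near the specialty's non-HBP cost level; users supply the real
    list via :func:`read_tariff_csv`.
    """
    base = default_specialty_costs().cost_per_admission
    entries: dict[str, tuple[str, float]] = {}
    case_mix: dict[str, float] = {}
    for i, spec in enumerate(SPECIALTIES):
        lo, hi = f"HBP-{i:02d}A", f"HBP-{i:02d}B"
        entries[lo] = (spec, base[spec] * 0.8)
        entries[hi] = (spec, base[spec] * 1.4)
        case_mix[lo] = 0.6
        case_mix[hi] = 0.4
    return TariffTable(entries=entries, case_mix=case_mix)


def read_specialty_costs_csv(path) -> SpecialtyCostTable:
    """Read a specialty cost table (columns: specialty, cost_per_admission_inr)."""
    df = pd.read_csv(path)
    return SpecialtyCostTable(
        dict(zip(df["specialty"], df["cost_per_admission_inr"].astype(float)))
    )


def read_tariff_csv(path) -> TariffTable:
    """Read an HBP tariff table (columns: code, specialty, cost, share)."""
    df = pd.read_csv(path)
    entries = {
        str(r["code"]): (str(r["specialty"]), float(r["cost"]))
        for _, r in df.iterrows()
    }
    case_mix = {str(r["code"]): float(r["share"]) for _, r in df.iterrows()}
    return TariffTable(entries=entries, case_mix=case_mix)
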