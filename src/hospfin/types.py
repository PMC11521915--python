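"""Core domain types for the blended district-hospital payment framework.

The framework pays a district hospital through three streams:

* outpatient care  — a risk-adjusted global budget (district covariates),
* inpatient care   — case-based bundled payments (tariff per admission),
* indirect services — a per-bed global budget (administration, registration,
  governance, biomedical waste, laundry, dietetics).

A :class:`HospitalRecord` carries everything the three streams need; a
:class:`HospitalPayout` carries their result for one hospital under one
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SPECIALTIES",
    "CADRES",
    "DistrictIndicators",
    "HospitalRecord",
    "HospitalPayout",
]

#: Clinical specialties of a secondary-level district hospital.
SPECIALTIES = (
    "Paediatrics",
    "General Medicine",
    "Obstetrics and gynaecology",
    "Ear Nose and Throat",
    "General Surgery",
    "Ophthalmology",
    "Orthopedics",
)

#: Staffing cadres tracked for the staffing-norm gap analysis.
CADRES = ("doctor", "paramedical", "support")

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class DistrictIndicators:
    """Demand-side covariates of one district.

    Parameters
    ----------
    district_id : str
        Unique district identifier.
    state : str
        State (or union territory) the district belongs to.
    city_tier : int
        Population-based city classification, 1 (largest) to 3.
    population : float
        District population in lakhs (hundred-thousands of persons).
    imr : float
        Infant mortality rate, deaths under age 1 per 1,000 live births.
        Used as the population health-need proxy.
    pct_young_old : float
        Percentage of the population under 5 or above 60 years of age.
    pct_public_utilization : float
        Percentage utilisation of public health services.
    """

    district_id: str
    state: str
    city_tier: int
    population: float
    imr: float
    pct_young_old: float
    pct_public_utilization: float

    def __post_init__(self) -> None:
        if self.city_tier not in (1, 2, 3):
            raise ValueError(f"city_tier must be 1, 2 or 3, got {self.city_tier}")
        if not self.population > 0:
            raise ValueError(f"population must be > 0, got {self.population}")
        if self.imr < 0:
            raise ValueError(f"imr must be >= 0, got {self.imr}")
        for name in ("pct_young_old", "pct_public_utilization"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class HospitalRecord:
    """One district-hospital facility record.

    ``op_cost``, ``ip_cost`` and ``indirect_cost`` are annual costs in INR;
    ``capital_cost`` is the capital stock (INR), not an annual flow.
    ``specialty_bed_shares`` maps specialty name to the fraction of inpatient
    beds it holds and must sum to one.
    """

    hospital_id: str
    district: DistrictIndicators
    beds: int
    specialty_bed_shares: dict[str, float]
    op_cost: float
    ip_cost: float
    indirect_cost: float
    capital_cost: float
    staffing: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beds < 1:
            raise ValueError(f"beds must be >= 1, got {self.beds}")
        shares = self.specialty_bed_shares
        if any(v < 0 for v in shares.values()):
            raise ValueError("specialty bed shares must be non-negative")
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"specialty bed shares must sum to 1, got {total}")
        for name in ("op_cost", "ip_cost", "indirect_cost", "capital_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.staffing.values()):
            raise ValueError("staffing headcounts must be >= 0")


@dataclass(frozen=True)
class HospitalPayout:
    """The three payment streams, and their total, for one hospital.

    ``provenance`` flags non-empirical inputs that entered the computation
    (e.g. ``"placeholder-tertiary-model"`` when the tertiary regression was
    not supplied by the user).
    """

    hospital_id: str
    scenario: str
    outpatient: float
    inpatient: float
    indirect: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("outpatient", "inpatient", "indirect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} stream must be >= 0")

    @property
    def total(self) -> float:
        """Sum of the three streams (exact by construction)."""
        return self.outpatient + self.inpatient + self.indirect
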