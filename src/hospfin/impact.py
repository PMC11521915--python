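"""National budget-impact rollup and comparison with actual expenditure.

Composes the three payment streams for each hospital (optionally under an
upgrade scenario), aggregates per-hospital payouts to national and state
summaries (means, ranges, max/min ratios, component shares), compares
proposed payouts with actual expenditure records, and converts currencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .indirect import indirect_budget
from .inpatient import default_specialty_profiles, inpatient_budget
from .outpatient import predict_outpatient_budget
from .scenarios import (
    ScenarioConfig,
    SalarySchedule,
    StaffingNorms,
    apply_iphs,
    apply_medical_college,
    default_salary_schedule,
    default_staffing_norms,
)
from .types import HospitalPayout, HospitalRecord

__all__ = [
    "CurrencyConfig",
    "NationalSummary",
    "allocate",
    "national_rollup",
    "compare_with_actual",
    "inr_to_usd",
    "percent_change",
    "payouts_to_frame",
]

logger = logging.getLogger(__name__)

STREAMS = ("outpatient", "inpatient", "indirect")
SCENARIOS = ("base", "iphs", "medical-college")


@dataclass(frozen=True)
class CurrencyConfig:
    """INR↔USD conversion (average rate of January 2024 by default)."""

    inr_per_usd: float = 82.54

    def __post_init__(self) -> None:
        if self.inr_per_usd <= 0:
            raise ValueError("exchange rate must be > 0")


@dataclass(frozen=True)
class NationalSummary:
    """Aggregate payout statistics across hospitals.

    ``stats`` has one row per stream plus ``total`` with columns mean, min,
    max, max_min_ratio (in INR/year); ``by_state`` has per-state min, max
    and ratio of the total payout; ``shares_pct`` gives each stream's
    percentage of the grand total.
    """

    stats: pd.DataFrame
    by_state: pd.DataFrame
    shares_pct: dict[str, float]
    n_hospitals: int


def allocate(
    hospital: HospitalRecord,
    config: ScenarioConfig | None = None,
    scenario: str = "base",
    norms: StaffingNorms | None = None,
    salaries: SalarySchedule | None = None,
    op_floor: float = 0.0,
) -> HospitalPayout:
    """Compute the three payment streams for one hospital under a scenario.

    ``base`` composes the secondary-care streams directly; ``iphs`` and
    ``medical-college`` delegate to the scenario adjustments. The total is
    the exact sum of the returned streams.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if config is None:
        config = ScenarioConfig()

    profiles = default_specialty_profiles(hospital.specialty_bed_shares)
    base = HospitalPayout(
        hospital_id=hospital.hospital_id,
        scenario="base",
        outpatient=predict_outpatient_budget(
            config.secondary_model, hospital.district, hospital.beds, floor=op_floor
        ),
        inpatient=inpatient_budget(
            hospital.beds, profiles, config.tariffs, config.nonpmjay_costs
        ),
        indirect=indirect_budget(hospital.beds, config.indirect_rates.rate_base),
    )
    if scenario == "base":
        return base
    if scenario == "iphs":
        return apply_iphs(
            hospital,
            base,
            norms or default_staffing_norms(),
            salaries or default_salary_schedule(),
            config,
            profiles=profiles,
        )
    return apply_medical_college(hospital, config, profiles=profiles)


def payouts_to_frame(payouts: Sequence[HospitalPayout]) -> pd.DataFrame:
    """One row per hospital payout, with the total column materialised."""
    return pd.DataFrame(
        {
            "hospital_id": [p.hospital_id for p in payouts],
            "scenario": [p.scenario for p in payouts],
            "outpatient": [p.outpatient for p in payouts],
            "inpatient": [p.inpatient for p in payouts],
            "indirect": [p.indirect for p in payouts],
            "total": [p.total for p in payouts],
        }
    )


def national_rollup(
    payouts: Sequence[HospitalPayout],
    states: Mapping[str, str] | None = None,
) -> NationalSummary:
    """Aggregate per-hospital payouts to a national summary.

    ``states`` optionally maps hospital_id to state for the per-state
    breakdown. Raw (unrounded) values are retained throughout; rounding the
    max/min ratio to one decimal and shares to whole percentages is a
    report-layer convention.
    """
    if not payouts:
        raise ValueError("cannot roll up an empty payout list")
    df = payouts_to_frame(payouts)

    rows = {}
    for col in (*STREAMS, "total"):
        s = df[col]
        rows[col] = {
            "mean": s.mean(),
            "min": s.min(),
            "max": s.max(),
            "max_min_ratio": s.max() / s.min() if s.min() > 0 else float("inf"),
        }
    stats = pd.DataFrame(rows).T

    if states:
        df = df.assign(state=df["hospital_id"].map(states))
        grouped = df.dropna(subset=["state"]).groupby("state")["total"]
        by_state = grouped.agg(["min", "max", "mean"])
        by_state["max_min_ratio"] = by_state["max"] / by_state["min"]
    else:
        by_state = pd.DataFrame(columns=["min", "max", "mean", "max_min_ratio"])

    grand = df["total"].sum()
    shares = {s: float(df[s].sum() / grand * 100.0) for s in STREAMS}
    return NationalSummary(
        stats=stats, by_state=by_state, shares_pct=shares, n_hospitals=len(payouts)
    )


def compare_with_actual(
    proposed: Sequence[HospitalPayout],
    actual: Mapping[str, float],
    flag_band_pct: float = 50.0,
) -> pd.DataFrame:
    """Per-hospital percentage deviation of proposed payout from actual.

    deviation = (proposed − actual) / actual × 100, computed over the key
    overlap. Hospitals with zero actual expenditure are flagged and
    excluded from the percentage; hospitals beyond ±``flag_band_pct`` are
    flagged. The frame carries summary values in ``attrs`` (min, max,
    n_flagged, n_zero_actual).
    """
    rows = []
    n_zero = 0
    for p in proposed:
        if p.hospital_id not in actual:
            continue
        act = actual[p.hospital_id]
        if act == 0:
            n_zero += 1
            rows.append(
                {
                    "hospital_id": p.hospital_id,
                    "proposed": p.total,
                    "actual": act,
                    "deviation_pct": float("nan"),
                    "flag": "zero-actual",
                }
            )
            continue
        dev = (p.total - act) / act * 100.0
        rows.append(
            {
                "hospital_id": p.hospital_id,
                "proposed": p.total,
                "actual": act,
                "deviation_pct": dev,
                "flag": "outside-band" if abs(dev) > flag_band_pct else "",
            }
        )
    if not rows:
        raise ValueError("no overlap between proposed payouts and actual records")
    if n_zero:
        logger.warning("%d hospitals with zero actual expenditure excluded", n_zero)
    df = pd.DataFrame(rows)
    valid = df["deviation_pct"].dropna()
    df.attrs["min_deviation_pct"] = float(valid.min()) if len(valid) else float("nan")
    df.attrs["max_deviation_pct"] = float(valid.max()) if len(valid) else float("nan")
    df.attrs["n_flagged"] = int((df["flag"] == "outside-band").sum())
    df.attrs["n_zero_actual"] = n_zero
    return df


def inr_to_usd(amount: float, fx: CurrencyConfig = CurrencyConfig()) -> float:
    """Convert INR to USD at the configured rate, unrounded."""
    return amount / fx.inr_per_usd


def percent_change(base: float, new: float) -> float:
    """(new − base) / base × 100."""
    if base <= 0:
        raise ValueError(f"base must be > 0, got {base}")
    return (new - base) / base * 100.0
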