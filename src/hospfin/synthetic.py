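"""Synthetic facility-level cost/indicator data.

The primary facility costing dataset behind the payment framework (27
district hospitals across nine states, expanded to 100 observations by
tier-stratified multivariate-normal simulation) is not publicly deposited.
This module generates datasets with the same statistical structure so every
downstream stage — the outpatient regression, the inpatient costing, the
per-bed indirect rate and the national budget-impact rollup — is fully
testable:

* :func:`generate_base_sample` draws a small stratified base sample whose
  outpatient cost is an exact linear predictor of the district covariates
  plus Gaussian noise, so parameter recovery is checkable against a known
  truth;
* :func:`expand_mvnd` performs the tier-stratified multivariate-normal
  expansion (default 7/29/64 = 100 records), with covariance shrinkage to
  keep the small tier-1 stratum non-singular, or a bootstrap alternative;
* :func:`generate_national_registry` stands in for the national bed
  registry of 845 district hospitals used in the budget-impact analysis.

All sampling is driven by explicit seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .outpatient import RiskAdjustmentModel, canonical_model, predict_outpatient_budget
from .types import CADRES, SPECIALTIES, DistrictIndicators, HospitalRecord

__all__ = [
    "GeneratorConfig",
    "generate_base_sample",
    "expand_mvnd",
    "generate_national_registry",
    "records_to_frame",
    "frame_to_records",
    "write_csv",
    "read_csv",
    "load_generator_config",
    "save_generator_config",
]

#: Baseline specialty bed-share profile of a district hospital.
BASE_BED_SHARES = {
    "Paediatrics": 0.12,
    "General Medicine": 0.25,
    "Obstetrics and gynaecology": 0.18,
    "Ear Nose and Throat": 0.06,
    "General Surgery": 0.15,
    "Ophthalmology": 0.06,
    "Orthopedics": 0.18,
}

# Covariate ranges: plausible Indian district-hospital values (population in
# lakhs, beds in counts, IMR per 1,000 live births). The ranges are shared
# across tiers — the tier classifies the *city*, while the district covariates
# vary independently of it — and tier-dependence of cost levels enters through
# the tier offsets of the generating model. This keeps the tier dummies from
# being collinear with population and beds.
_TIER_RANGES: dict[int, dict[str, tuple[float, float]]] = {
    1: {"population": (3, 90), "beds": (100, 700), "imr": (15, 60)},
    2: {"population": (3, 90), "beds": (100, 700), "imr": (15, 60)},
    3: {"population": (3, 90), "beds": (100, 700), "imr": (15, 60)},
}
_PCT_YOUNG_OLD_RANGE = (16.0, 28.0)
_PCT_UTIL_RANGE = {1: (20.0, 60.0), 2: (20.0, 60.0), 3: (20.0, 60.0)}

#: Per-bed annual indirect cost level the generator targets (INR/bed/year).
INDIRECT_RATE_LEVEL = 163_969.0
#: Approximate inpatient cost per occupied-bed-year implied by the default
#: admission profile (BOR ~0.8, ALOS ~4 days, ~12k INR per admission).
_IP_COST_PER_BED = 876_000.0
_CAPITAL_PER_BED = 2_000_000.0

_STATES = (
    "Andhra Pradesh",
    "Assam",
    "Bihar",
    "Goa",
    "Gujarat",
    "Haryana",
    "Himachal Pradesh",
    "Jharkhand",
    "Karnataka",
    "Kerala",
    "Madhya Pradesh",
    "Maharashtra",
    "Odisha",
    "Punjab",
    "Rajasthan",
    "Tamil Nadu",
    "Telangana",
    "Uttar Pradesh",
    "Uttarakhand",
    "West Bengal",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic facility generator.

    ``coefficient_truth`` is the risk-adjustment model used to generate
    outpatient costs; ``noise_sd`` the SD of the additive Gaussian noise
    (INR/year); ``covariance_shrinkage`` the λ in
    Σ' = (1−λ)Σ + λ·diag(Σ) applied before multivariate-normal sampling.
    """

    n_base_per_tier: dict[int, int] = field(
        default_factory=lambda: {1: 5, 2: 9, 3: 13}
    )
    expansion_counts: dict[int, int] = field(
        default_factory=lambda: {1: 7, 2: 29, 3: 64}
    )
    seed: int = 0
    coefficient_truth: RiskAdjustmentModel = field(default_factory=canonical_model)
    noise_sd: float = 20_000_000.0
    covariance_shrinkage: float = 0.1
    expansion_method: Literal["mvnd", "bootstrap"] = "mvnd"
    op_cost_floor: float = 0.0

    def __post_init__(self) -> None:
        if any(t not in (1, 2, 3) for t in self.n_base_per_tier):
            raise ValueError("base tiers must be in {1, 2, 3}")
        if any(n < 2 for n in self.n_base_per_tier.values()):
            raise ValueError("need at least 2 base records per tier")
        if any(n < 1 for n in self.expansion_counts.values()):
            raise ValueError("expansion counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.covariance_shrinkage <= 1.0:
            raise ValueError("covariance_shrinkage must lie in [0, 1]")
        if self.expansion_method not in ("mvnd", "bootstrap"):
            raise ValueError(f"unknown expansion method {self.expansion_method!r}")


# numeric fields entering the multivariate-normal expansion, in order
_NUMERIC_FIELDS = (
    "population",
    "imr",
    "pct_young_old",
    "pct_public_utilization",
    "beds",
    "staff_doctor",
    "staff_paramedical",
    "staff_support",
    "op_cost",
    "ip_cost",
    "indirect_cost",
    "capital_cost",
)


def _sample_shares(rng: np.random.Generator) -> dict[str, float]:
    alpha = np.array([BASE_BED_SHARES[s] for s in SPECIALTIES]) * 60.0
    draw = rng.dirichlet(alpha)
    return {s: float(v) for s, v in zip(SPECIALTIES, draw)}


def _make_record(
    idx: int,
    tier: int,
    state: str,
    rng: np.random.Generator,
    config: GeneratorConfig,
    prefix: str = "DH",
) -> HospitalRecord:
    rr = _TIER_RANGES[tier]
    district = DistrictIndicators(
        district_id=f"{prefix}-{idx:04d}",
        state=state,
        city_tier=tier,
        population=float(rng.uniform(*rr["population"])),
        imr=float(rng.uniform(*rr["imr"])),
        pct_young_old=float(rng.uniform(*_PCT_YOUNG_OLD_RANGE)),
        pct_public_utilization=float(rng.uniform(*_PCT_UTIL_RANGE[tier])),
    )
    beds = int(round(rng.uniform(*rr["beds"])))
    op_cost = predict_outpatient_budget(
        config.coefficient_truth, district, beds, floor=-np.inf
    )
    if config.noise_sd > 0:
        op_cost += float(rng.normal(0.0, config.noise_sd))
    op_cost = max(op_cost, config.op_cost_floor)
    ip_cost = beds * _IP_COST_PER_BED * float(rng.lognormal(0.0, 0.20))
    indirect_cost = beds * INDIRECT_RATE_LEVEL * float(rng.lognormal(0.0, 0.25))
    capital_cost = beds * _CAPITAL_PER_BED * float(rng.lognormal(0.0, 0.30))
    staffing = {
        "doctor": float(np.round(beds * 0.18 * rng.lognormal(0.0, 0.15))),
        "paramedical": float(np.round(beds * 0.55 * rng.lognormal(0.0, 0.15))),
        "support": float(np.round(beds * 0.40 * rng.lognormal(0.0, 0.15))),
    }
    return HospitalRecord(
        hospital_id=f"{prefix}-{idx:04d}",
        district=district,
        beds=beds,
        specialty_bed_shares=_sample_shares(rng),
        op_cost=op_cost,
        ip_cost=ip_cost,
        indirect_cost=indirect_cost,
        capital_cost=capital_cost,
        staffing=staffing,
    )


def generate_base_sample(config: GeneratorConfig) -> list[HospitalRecord]:
    """Draw the stratified base facility sample.

    Outpatient cost is the exact linear predictor of
    ``config.coefficient_truth`` plus N(0, noise_sd²) noise, floored at
    ``config.op_cost_floor``, so an OLS refit can be validated against the
    generating coefficients. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    records: list[HospitalRecord] = []
    idx = 0
    for tier in sorted(config.n_base_per_tier):
        for _ in range(config.n_base_per_tier[tier]):
            state = _STATES[int(rng.integers(len(_STATES)))]
            records.append(_make_record(idx, tier, state, rng, config))
            idx += 1
    return records


def _record_to_numeric(rec: HospitalRecord) -> np.ndarray:
    d = rec.district
    return np.array(
        [
            d.population,
            d.imr,
            d.pct_young_old,
            d.pct_public_utilization,
            float(rec.beds),
            rec.staffing.get("doctor", 0.0),
            rec.staffing.get("paramedical", 0.0),
            rec.staffing.get("support", 0.0),
            rec.op_cost,
            rec.ip_cost,
            rec.indirect_cost,
            rec.capital_cost,
        ]
    )


def _numeric_to_record(
    idx: int,
    tier: int,
    state: str,
    vec: np.ndarray,
    shares: dict[str, float],
    floor_op: float,
) -> HospitalRecord:
    # clip each sampled field to its physical bounds
    population = max(float(vec[0]), 0.1)
    imr = max(float(vec[1]), 0.0)
    pct_young_old = float(np.clip(vec[2], 0.0, 100.0))
    pct_util = float(np.clip(vec[3], 0.0, 100.0))
    beds = max(int(round(vec[4])), 1)
    staffing = {
        "doctor": max(float(np.round(vec[5])), 0.0),
        "paramedical": max(float(np.round(vec[6])), 0.0),
        "support": max(float(np.round(vec[7])), 0.0),
    }
    district = DistrictIndicators(
        district_id=f"SIM-{idx:04d}",
        state=state,
        city_tier=tier,
        population=population,
        imr=imr,
        pct_young_old=pct_young_old,
        pct_public_utilization=pct_util,
    )
    return HospitalRecord(
        hospital_id=f"SIM-{idx:04d}",
        district=district,
        beds=beds,
        specialty_bed_shares=shares,
        op_cost=max(float(vec[8]), floor_op),
        ip_cost=max(float(vec[9]), 0.0),
        indirect_cost=max(float(vec[10]), 0.0),
        capital_cost=max(float(vec[11]), 0.0),
        staffing=staffing,
    )


def expand_mvnd(
    base: Sequence[HospitalRecord], config: GeneratorConfig
) -> list[HospitalRecord]:
    """Tier-stratified multivariate-normal expansion of a base sample.

    Per tier in ``config.expansion_counts``, estimates the mean vector and
    covariance of the numeric facility fields, shrinks the covariance by
    Σ' = (1−λ)Σ + λ·diag(Σ), samples the configured count and clips to the
    field invariants. Specialty bed shares are set to the tier's mean base
    profile (renormalised). With ``expansion_method="bootstrap"``, records
    are instead resampled with replacement within each tier.

    Raises
    ------
    ValueError
        If a requested tier is absent from (or has < 2 records in) the base
        sample, or the within-tier covariance is singular with λ = 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    by_tier: dict[int, list[HospitalRecord]] = {}
    for rec in base:
        by_tier.setdefault(rec.district.city_tier, []).append(rec)

    out: list[HospitalRecord] = []
    idx = 0
    for tier in sorted(config.expansion_counts):
        n = config.expansion_counts[tier]
        tier_recs = by_tier.get(tier, [])
        if len(tier_recs) < 2:
            raise ValueError(
                f"tier {tier} has {len(tier_recs)} base records; need >= 2 to expand"
            )
        states = [r.district.state for r in tier_recs]

        if config.expansion_method == "bootstrap":
            picks = rng.integers(len(tier_recs), size=n)
            for k in picks:
                src = tier_recs[int(k)]
                out.append(
                    replace(
                        src,
                        hospital_id=f"SIM-{idx:04d}",
                        district=replace(src.district, district_id=f"SIM-{idx:04d}"),
                    )
                )
                idx += 1
            continue

        data = np.stack([_record_to_numeric(r) for r in tier_recs])
        mean = data.mean(axis=0)
        cov = np.cov(data, rowvar=False)
        lam = config.covariance_shrinkage
        cov_shrunk = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))
        # degenerate columns (zero variance) are legitimate: the distribution
        # collapses to the base value in that coordinate
        eigvals = np.linalg.eigvalsh(cov_shrunk)
        scale = max(np.abs(eigvals).max(), 1.0)
        if eigvals.min() < -1e-9 * scale:
            raise ValueError(
                f"tier {tier} covariance is not positive semidefinite with "
                f"shrinkage λ={lam}; increase covariance_shrinkage"
            )
        if lam == 0.0 and eigvals.min() < 1e-12 * scale:
            raise ValueError(
                f"tier {tier} covariance is singular with λ=0; "
                "set covariance_shrinkage > 0"
            )
        # project out numerically-negative eigenvalues before sampling
        w, v = np.linalg.eigh((cov_shrunk + cov_shrunk.T) / 2.0)
        cov_psd = (v * np.clip(w, 0.0, None)) @ v.T
        draws = rng.multivariate_normal(
            mean, cov_psd, size=n, method="eigh", check_valid="ignore"
        )

        # tier-mean compositional profile, renormalised
        share_mat = np.array(
            [[r.specialty_bed_shares[s] for s in SPECIALTIES] for r in tier_recs]
        )
        mean_shares = share_mat.mean(axis=0)
        mean_shares = mean_shares / mean_shares.sum()
        shares = {s: float(v) for s, v in zip(SPECIALTIES, mean_shares)}

        for row in draws:
            state = states[int(rng.integers(len(states)))]
            out.append(
                _numeric_to_record(idx, tier, state, row, dict(shares), config.op_cost_floor)
            )
            idx += 1
    return out


def generate_national_registry(
    n_hospitals: int = 845, seed: int = 0
) -> list[HospitalRecord]:
    """Synthetic national district-hospital bed registry.

    Stands in for the national facility registry (845 district hospitals in
    scope for the budget-impact analysis): one record per hospital with bed
    count, state label and district indicators, grouped over a fixed list
    of states. Tier composition follows the 7/29/64% stratification of the
    modelling dataset. Deterministic per seed.
    """
    if n_hospitals < 1:
        raise ValueError(f"n_hospitals must be >= 1, got {n_hospitals}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    config = GeneratorConfig(seed=seed)
    tiers = rng.choice([1, 2, 3], size=n_hospitals, p=[0.07, 0.29, 0.64])
    records = []
    for i in range(n_hospitals):
        state = _STATES[int(rng.integers(len(_STATES)))]
        records.append(
            _make_record(i, int(tiers[i]), state, rng, config, prefix="NHR")
        )
    return records


# -- tabular round-trip ------------------------------------------------------

def records_to_frame(records: Sequence[HospitalRecord]) -> pd.DataFrame:
    """One row per hospital; specialty shares and staffing as wide columns."""
    rows = []
    for r in records:
        d = r.district
        row = {
            "hospital_id": r.hospital_id,
            "district_id": d.district_id,
            "state": d.state,
            "city_tier": d.city_tier,
            "population": d.population,
            "imr": d.imr,
            "pct_young_old": d.pct_young_old,
            "pct_public_utilization": d.pct_public_utilization,
            "beds": r.beds,
            "op_cost": r.op_cost,
            "ip_cost": r.ip_cost,
            "indirect_cost": r.indirect_cost,
            "capital_cost": r.capital_cost,
        }
        for c in CADRES:
            row[f"staff_{c}"] = r.staffing.get(c, 0.0)
        for s in SPECIALTIES:
            row[f"share_{s}"] = r.specialty_bed_shares.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[HospitalRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for _, row in df.iterrows():
        district = DistrictIndicators(
            district_id=str(row["district_id"]),
            state=str(row["state"]),
            city_tier=int(row["city_tier"]),
            population=float(row["population"]),
            imr=float(row["imr"]),
            pct_young_old=float(row["pct_young_old"]),
            pct_public_utilization=float(row["pct_public_utilization"]),
        )
        records.append(
            HospitalRecord(
                hospital_id=str(row["hospital_id"]),
                district=district,
                beds=int(row["beds"]),
                specialty_bed_shares={
                    s: float(row[f"share_{s}"]) for s in SPECIALTIES
                },
                op_cost=float(row["op_cost"]),
                ip_cost=float(row["ip_cost"]),
                indirect_cost=float(row["indirect_cost"]),
                capital_cost=float(row["capital_cost"]),
                staffing={c: float(row[f"staff_{c}"]) for c in CADRES},
            )
        )
    return records


def write_csv(records: Sequence[HospitalRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_csv(path) -> list[HospitalRecord]:
    return frame_to_records(pd.read_csv(path))


def save_generator_config(config: GeneratorConfig, path) -> None:
    """Write a generator configuration as YAML (JSON is a YAML subset)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_generator_config(path) -> GeneratorConfig:
    """Read a generator configuration from a YAML or JSON document."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("n_base_per_tier", "expansion_counts"):
        if key in data and data[key] is not None:
            data[key] = {int(t): int(n) for t, n in data[key].items()}
    truth = data.get("coefficient_truth")
    if isinstance(truth, dict):
        data["coefficient_truth"] = RiskAdjustmentModel(**truth)
    return GeneratorConfig(**data)
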