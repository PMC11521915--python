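"""Risk-adjusted global budget for outpatient care.

The outpatient stream is a prospective global budget set by a multiple
linear regression of annual outpatient cost on demand- and supply-side
district covariates:

    cost = b0 + b_t2*[tier2] + b_t3*[tier3] + b_pop*population
              + b_beds*beds + b_imr*IMR + b_age*age% + b_util*util%

with tier-1 cities as the reference category. Population is measured in
lakhs. The module fits the model by OLS with the standard diagnostic
battery (normality of regressand and residuals, homoscedasticity,
multicollinearity) and also ships the published coefficient set so budgets
can be allocated without refitting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan, lilliefors
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .types import DistrictIndicators, HospitalRecord

__all__ = [
    "RiskAdjustmentModel",
    "RegressionDiagnostics",
    "COVARIATE_NAMES",
    "fit_ols",
    "canonical_model",
    "predict_outpatient_budget",
    "classify_city_tier",
    "design_matrix",
    "model_to_json",
    "model_from_json",
    "summary_table",
]

logger = logging.getLogger(__name__)

#: Design-matrix column order (after the intercept).
COVARIATE_NAMES = (
    "tier2",
    "tier3",
    "population",
    "beds",
    "imr",
    "pct_young_old",
    "pct_public_utilization",
)

# City-tier classification thresholds on district population, in lakhs.
TIER1_MIN_POPULATION_LAKHS = 50.0
TIER2_MIN_POPULATION_LAKHS = 10.0


@dataclass(frozen=True)
class RiskAdjustmentModel:
    """Coefficient vector of the outpatient risk-adjustment regression.

    All coefficients are in INR per year per unit of the covariate
    (population in lakhs, beds in counts, IMR in deaths per 1,000 live
    births, age and utilisation in percentage points). Tier offsets apply
    on top of the tier-1 intercept.
    """

    intercept: float
    tier2_offset: float
    tier3_offset: float
    beta_population: float
    beta_beds: float
    beta_imr: float
    beta_age: float
    beta_util: float
    r2: float = float("nan")
    adj_r2: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isnan(self.r2) and not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")
        if (
            not np.isnan(self.r2)
            and not np.isnan(self.adj_r2)
            and self.adj_r2 > self.r2 + 1e-12
        ):
            raise ValueError("adjusted R^2 cannot exceed R^2")

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector ordered as (intercept, *COVARIATE_NAMES)."""
        return np.array(
            [
                self.intercept,
                self.tier2_offset,
                self.tier3_offset,
                self.beta_population,
                self.beta_beds,
                self.beta_imr,
                self.beta_age,
                self.beta_util,
            ]
        )


@dataclass(frozen=True)
class RegressionDiagnostics:
    """Diagnostic battery of one OLS fit.

    ``ks_p_regressand`` / ``ks_p_residuals`` are Lilliefors-corrected
    Kolmogorov–Smirnov p-values for normality (parameters estimated from
    the data); ``bp_p`` is the Breusch–Pagan LM p-value for
    homoscedasticity; ``vif`` maps each covariate to its variance
    inflation factor.
    """

    ks_p_regressand: float
    ks_p_residuals: float
    bp_p: float
    vif: dict[str, float]
    r2: float
    adj_r2: float

    def __post_init__(self) -> None:
        for name in ("ks_p_regressand", "ks_p_residuals", "bp_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a p-value in [0, 1], got {v}")
        if any(v < 1.0 - 1e-9 for v in self.vif.values()):
            raise ValueError("VIF values cannot be below 1")


def classify_city_tier(
    population_lakhs: float,
    *,
    tier1_min: float = TIER1_MIN_POPULATION_LAKHS,
    tier2_min: float = TIER2_MIN_POPULATION_LAKHS,
) -> int:
    """Classify a city into tier 1/2/3 from its population in lakhs."""
    if population_lakhs > tier1_min:
        return 1
    if population_lakhs >= tier2_min:
        return 2
    return 3


def _covariate_row(district: DistrictIndicators, beds: float) -> np.ndarray:
    return np.array(
        [
            1.0 if district.city_tier == 2 else 0.0,
            1.0 if district.city_tier == 3 else 0.0,
            district.population,
            float(beds),
            district.imr,
            district.pct_young_old,
            district.pct_public_utilization,
        ]
    )


def design_matrix(records: Sequence[HospitalRecord]) -> pd.DataFrame:
    """Covariate matrix (without intercept) for a set of facility records."""
    rows = [_covariate_row(r.district, r.beds) for r in records]
    return pd.DataFrame(rows, columns=list(COVARIATE_NAMES))


def fit_ols(
    records: Sequence[HospitalRecord],
) -> tuple[RiskAdjustmentModel, RegressionDiagnostics]:
    """Fit the outpatient risk-adjustment regression by OLS.

    Requires at least 10 records with tiers 2 and 3 both represented
    (tier 1 is the reference level of the city-type factor).

    Returns
    -------
    (RiskAdjustmentModel, RegressionDiagnostics)

    Raises
    ------
    ValueError
        On too few records, a missing tier level, or a singular design
        (the error names the collinear columns).
    """
    if len(records) < 10:
        raise ValueError(f"need >= 10 records to fit, got {len(records)}")
    tiers = {r.district.city_tier for r in records}
    if not {2, 3} <= tiers:
        raise ValueError(
            f"tiers 2 and 3 must both be present (tier 1 is the reference); got {sorted(tiers)}"
        )

    X = design_matrix(records)
    y = np.array([r.op_cost for r in records], dtype=float)
    if len(records) < X.shape[1] + 1:
        raise ValueError("fewer rows than regression parameters")

    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for col in X.columns:
            reduced = Xc.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(col)
        raise ValueError(f"singular design matrix; collinear columns: {bad}")

    res = sm.OLS(y, Xc).fit()
    params = res.params.to_numpy()
    model = RiskAdjustmentModel(
        intercept=params[0],
        tier2_offset=params[1],
        tier3_offset=params[2],
        beta_population=params[3],
        beta_beds=params[4],
        beta_imr=params[5],
        beta_age=params[6],
        beta_util=params[7],
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
    )

    resid = np.asarray(res.resid)
    with warnings.catch_warnings():
        # lilliefors warns when p is outside the tabulated range
        warnings.simplefilter("ignore")
        _, ks_p_y = lilliefors(y, dist="norm")
        _, ks_p_e = lilliefors(resid, dist="norm")
    if resid.std() < 1e-8 * max(1.0, np.abs(y).mean()):
        # degenerate (noiseless) fit: the BP auxiliary regression is vacuous
        bp_p = 1.0
    else:
        _, bp_p, _, _ = het_breuschpagan(resid, Xc.to_numpy())
    Xnp = Xc.to_numpy()
    vif = {
        name: float(variance_inflation_factor(Xnp, i + 1))
        for i, name in enumerate(COVARIATE_NAMES)
    }
    diag = RegressionDiagnostics(
        ks_p_regressand=float(np.clip(ks_p_y, 0.0, 1.0)),
        ks_p_residuals=float(np.clip(ks_p_e, 0.0, 1.0)),
        bp_p=float(np.clip(bp_p, 0.0, 1.0)),
        vif=vif,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
    )
    return model, diag


def canonical_model() -> RiskAdjustmentModel:
    """The published risk-adjustment coefficient set for secondary care.

    These are the coefficients of the outpatient-cost regression on the
    simulated 100-facility dataset (tier-1 reference), used to allocate
    outpatient budgets to all district hospitals without refitting.
    """
    return RiskAdjustmentModel(
        intercept=75_400_000.0,
        tier2_offset=-34_300_000.0,
        tier3_offset=-51_400_000.0,
        beta_population=60_858.0,
        beta_beds=89_121.0,
        beta_imr=565_977.0,
        beta_age=-1_673_450.0,
        beta_util=-20_079.0,
        r2=0.5603,
        adj_r2=0.5268,
    )


def predict_outpatient_budget(
    model: RiskAdjustmentModel,
    district: DistrictIndicators,
    beds: int,
    *,
    floor: float = 0.0,
) -> float:
    """Annual outpatient global budget (INR/year) for one hospital.

    Evaluates the linear predictor; a negative prediction (possible for
    small tier-3 hospitals with a high young/old share) is floored at
    ``floor`` with a logged warning.
    """
    if beds < 1:
        raise ValueError(f"beds must be >= 1, got {beds}")
    x = np.concatenate([[1.0], _covariate_row(district, beds)])
    value = float(x @ model.coefficients)
    if value < floor:
        logger.warning(
            "outpatient budget %.0f INR for %s floored at %.0f",
            value,
            district.district_id,
            floor,
        )
        return floor
    return value


# -- serialisation ----------------------------------------------------------

def model_to_json(model: RiskAdjustmentModel) -> str:
    """Serialise a coefficient set to a JSON document."""
    return json.dumps(asdict(model), indent=2)


def model_from_json(text: str) -> RiskAdjustmentModel:
    """Inverse of :func:`model_to_json`."""
    return RiskAdjustmentModel(**json.loads(text))


def summary_table(records: Sequence[HospitalRecord]) -> str:
    """Plain-text fit summary: coefficient, SE and 95% CI per regressor."""
    X = sm.add_constant(design_matrix(records), has_constant="add")
    y = np.array([r.op_cost for r in records], dtype=float)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    lines = [f"{'term':<26}{'coef':>16}{'SE':>16}{'95% CI':>36}"]
    for i, name in enumerate(["intercept", *COVARIATE_NAMES]):
        lines.append(
            f"{name:<26}{res.params.iloc[i]:>16,.0f}{res.bse.iloc[i]:>16,.0f}"
            f"{'(' + format(ci.iloc[i, 0], ',.0f') + ', ' + format(ci.iloc[i, 1], ',.0f') + ')':>36}"
        )
    lines.append(f"R2 {res.rsquared:.4f}   adjusted R2 {res.rsquared_adj:.4f}")
    return "\n".join(lines)
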