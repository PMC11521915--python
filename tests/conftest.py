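import pytest

from hospfin.outpatient import canonical_model
from hospfin.synthetic import GeneratorConfig, expand_mvnd, generate_base_sample
from hospfin.types import DistrictIndicators, HospitalRecord, SPECIALTIES


@pytest.fixture(scope="session")
def published_model():
    return canonical_model()


@pytest.fixture(scope="session")
def base_sample():
    """The default 27-hospital stratified base sample."""
    return generate_base_sample(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def expanded_sample(base_sample):
    """The 100-record tier-stratified multivariate-normal expansion."""
    return expand_mvnd(base_sample, GeneratorConfig(seed=11))


def make_district(
    tier=3, population=20.0, imr=40.0, young_old=20.0, util=30.0, state="Tamil Nadu"
) -> DistrictIndicators:
    return DistrictIndicators(
        district_id=f"D-t{tier}",
        state=state,
        city_tier=tier,
        population=population,
        imr=imr,
        pct_young_old=young_old,
        pct_public_utilization=util,
    )


def make_hospital(
    beds=300,
    tier=3,
    op_cost=50e6,
    ip_cost=200e6,
    indirect_cost=40e6,
    capital_cost=500e6,
    staffing=None,
    **district_kwargs,
) -> HospitalRecord:
    n = len(SPECIALTIES)
    return HospitalRecord(
        hospital_id=f"H-{beds}-t{tier}",
        district=make_district(tier=tier, **district_kwargs),
        beds=beds,
        specialty_bed_shares={s: 1.0 / n for s in SPECIALTIES},
        op_cost=op_cost,
        ip_cost=ip_cost,
        indirect_cost=indirect_cost,
        capital_cost=capital_cost,
        staffing=staffing or {"doctor": 50, "paramedical": 160, "support": 110},
    )


@pytest.fixture
def district_factory():
    return make_district


@pytest.fixture
def hospital_factory():
    return make_hospital
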