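"""Tests of the IPHS and medical-college upgrade scenarios."""

import pytest

from hospfin.impact import allocate
from hospfin.indirect import IndirectRateConfig
from hospfin.inpatient import default_specialty_costs, default_tariff_table
from hospfin.outpatient import canonical_model
from hospfin.scenarios import (
    SalarySchedule,
    ScenarioConfig,
    StaffingNorms,
    apply_iphs,
    apply_medical_college,
    capital_gap_annualization,
    default_salary_schedule,
    default_staffing_norms,
    placeholder_tertiary_model,
    staffing_shortfall_cost,
)

from conftest import make_hospital

SALARIES = SalarySchedule(
    annual_salary={"doctor": 1_200_000.0, "paramedical": 400_000.0, "support": 250_000.0}
)


def flat_norms(doctor=0.0, paramedical=0.0, support=0.0):
    return StaffingNorms(
        steps=((0, {"doctor": doctor, "paramedical": paramedical, "support": support}),)
    )


class TestStaffingShortfall:
    def test_no_shortfall_when_staffing_meets_norms(self):
        norms = flat_norms(doctor=10, paramedical=20, support=15)
        current = {"doctor": 12, "paramedical": 20, "support": 30}
        assert staffing_shortfall_cost(current, norms, 200, SALARIES) == 0.0

    def test_two_doctor_gap(self):
        norms = flat_norms(doctor=12)
        assert staffing_shortfall_cost({"doctor": 10}, norms, 200, SALARIES) == (
            pytest.approx(2_400_000.0)
        )

    def test_mixed_gaps_sum_without_offsetting(self):
        norms = flat_norms(doctor=5, paramedical=23, support=35)
        current = {"doctor": 50, "paramedical": 20, "support": 30}
        # doctor surplus must not offset the 3 paramedical + 5 support gaps
        assert staffing_shortfall_cost(current, norms, 200, SALARIES) == (
            pytest.approx(3 * 400_000 + 5 * 250_000)
        )

    def test_missing_salary_raises(self):
        norms = flat_norms(doctor=5)
        with pytest.raises(KeyError, match="doctor"):
            staffing_shortfall_cost({}, norms, 100, SalarySchedule({"support": 1.0}))

    def test_norm_steps_non_decreasing_in_beds(self):
        norms = default_staffing_norms()
        reqs = [norms.required(b) for b in (50, 150, 250, 350, 450, 550)]
        for lo, hi in zip(reqs, reqs[1:]):
            assert all(hi[c] >= lo[c] for c in lo)
        with pytest.raises(ValueError, match="non-decreasing"):
            StaffingNorms(steps=((0, {"doctor": 10}), (100, {"doctor": 5})))


@pytest.mark.parametrize(
    "capital,fraction,expected",
    [(100.0, 0.2, 20.0), (0.0, 0.2, 0.0), (250_000_000.0, 0.2, 50_000_000.0)],
)
def test_capital_annualization(capital, fraction, expected):
    assert capital_gap_annualization(capital, fraction) == pytest.approx(expected)


class TestIphs:
    def test_null_upgrade_leaves_payout_unchanged(self):
        h = make_hospital(beds=200, capital_cost=0.0)
        base = allocate(h)
        norms = flat_norms(
            doctor=h.staffing["doctor"],
            paramedical=h.staffing["paramedical"],
            support=h.staffing["support"],
        )
        cfg = ScenarioConfig(iphs_bed_uplift=1.0)
        up = apply_iphs(h, base, norms, SALARIES, cfg)
        assert up.outpatient == pytest.approx(base.outpatient)
        assert up.inpatient == pytest.approx(base.inpatient)
        assert up.indirect == pytest.approx(base.indirect)

    def test_bed_uplift_scales_inpatient_stream(self):
        h = make_hospital(beds=200, capital_cost=0.0)
        base = allocate(h)
        norms = flat_norms()
        up = apply_iphs(h, base, norms, SALARIES, ScenarioConfig(iphs_bed_uplift=1.5))
        assert up.inpatient == pytest.approx(1.5 * base.inpatient, rel=1e-9)

    def test_total_never_below_base(self):
        h = make_hospital(beds=300)
        base = allocate(h)
        up = apply_iphs(
            h,
            base,
            default_staffing_norms(),
            default_salary_schedule(),
            ScenarioConfig(iphs_bed_uplift=1.2),
        )
        assert up.total >= base.total
        assert up.indirect == base.indirect  # indirect stream unchanged

    def test_shortfall_split_moves_cost_between_streams(self):
        h = make_hospital(beds=300, capital_cost=0.0, staffing={"doctor": 0, "paramedical": 0, "support": 0})
        base = allocate(h)
        norms = flat_norms(doctor=10)
        all_op = apply_iphs(h, base, norms, SALARIES, ScenarioConfig(op_shortfall_split=1.0))
        all_ip = apply_iphs(h, base, norms, SALARIES, ScenarioConfig(op_shortfall_split=0.0))
        assert all_op.outpatient - base.outpatient == pytest.approx(12_000_000.0)
        assert all_ip.outpatient == pytest.approx(base.outpatient)
        assert all_op.total == pytest.approx(all_ip.total)


class TestMedicalCollege:
    def test_one_bed_indirect_component(self):
        h = make_hospital(beds=1)
        out = apply_medical_college(h, ScenarioConfig())
        assert out.indirect == pytest.approx(294_441.0)

    def test_identity_configuration_reproduces_base(self):
        h = make_hospital(beds=250)
        base = allocate(h)
        cfg = ScenarioConfig(
            tertiary_model=canonical_model(),
            tertiary_tariffs=default_tariff_table(),
            tertiary_nonpmjay_costs=default_specialty_costs(),
            indirect_rates=IndirectRateConfig(
                rate_medical_college=IndirectRateConfig().rate_base
            ),
        )
        up = apply_medical_college(h, cfg)
        assert up.outpatient == pytest.approx(base.outpatient)
        assert up.inpatient == pytest.approx(base.inpatient)
        assert up.indirect == pytest.approx(base.indirect)
        assert up.provenance == ()

    def test_tariff_multiplier_raises_inpatient_by_123_percent(self):
        h = make_hospital(beds=250)
        base = allocate(h)
        up = apply_medical_college(h, ScenarioConfig(tertiary_tariff_multiplier=2.23))
        assert up.inpatient == pytest.approx(2.23 * base.inpatient, rel=1e-9)
        assert (up.inpatient - base.inpatient) / base.inpatient == pytest.approx(1.23)

    def test_placeholder_flagged_and_refusable(self):
        h = make_hospital(beds=250)
        up = apply_medical_college(h, ScenarioConfig())
        assert "placeholder-tertiary-model" in up.provenance
        with pytest.raises(ValueError, match="placeholder"):
            apply_medical_college(h, ScenarioConfig(allow_placeholders=False))

    def test_placeholder_model_scales_secondary_prediction(self):
        from hospfin.outpatient import predict_outpatient_budget

        h = make_hospital(beds=250)
        sec = predict_outpatient_budget(canonical_model(), h.district, h.beds)
        ter = predict_outpatient_budget(placeholder_tertiary_model(), h.district, h.beds)
        assert ter == pytest.approx(1.06 * sec, rel=1e-12)


def test_scenario_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(capital_annual_fraction=0.0)
    with pytest.raises(ValueError):
        ScenarioConfig(iphs_bed_uplift=0.9)
    with pytest.raises(ValueError):
        ScenarioConfig(op_shortfall_split=1.5)


def test_norms_and_salaries_csv_round_trip(tmp_path):
    import pandas as pd

    from hospfin.scenarios import read_norms_csv, read_salaries_csv

    norms = default_staffing_norms()
    rows = [{"min_beds": mb, **req} for mb, req in norms.steps]
    p = tmp_path / "norms.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    assert read_norms_csv(p).required(320) == norms.required(320)

    sal = default_salary_schedule()
    q = tmp_path / "salaries.csv"
    pd.DataFrame(
        {"cadre": list(sal.annual_salary), "annual_salary_inr": list(sal.annual_salary.values())}
    ).to_csv(q, index=False)
    assert read_salaries_csv(q).annual_salary == sal.annual_salary
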