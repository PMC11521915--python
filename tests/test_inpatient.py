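"""Tests of the case-based bundled payment for inpatient care."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hospfin.inpatient import (
    SpecialtyCostTable,
    SpecialtyProfile,
    TariffTable,
    default_specialty_costs,
    default_specialty_profiles,
    default_tariff_table,
    economic_cost,
    expected_admissions,
    inpatient_budget,
    read_specialty_costs_csv,
    read_tariff_csv,
    weighted_specialty_cost,
)
from hospfin.types import SPECIALTIES

PUBLISHED_COSTS = {
    "Paediatrics": 10_415,
    "General Medicine": 10_481,
    "Obstetrics and gynaecology": 13_286,
    "Ear Nose and Throat": 14_104,
    "General Surgery": 13_011,
    "Ophthalmology": 9_867,
    "Orthopedics": 13_925,
}


def profile(spec="General Medicine", share=1.0, alos=4.0, bor=0.8, pmjay=0.0):
    return SpecialtyProfile(
        specialty=spec, bed_share=share, alos=alos, bor=bor, pmjay_share=pmjay
    )


class TestExpectedAdmissions:
    @pytest.mark.parametrize(
        "beds,share,bor,alos,expected",
        [
            (1, 1.0, 1.0, 365.0, 1.0),
            (100, 1.0, 0.8, 4.0, 7_300.0),
            (100, 1.0, 0.0, 4.0, 0.0),
            (0, 1.0, 0.9, 3.0, 0.0),
        ],
    )
    def test_hand_arithmetic(self, beds, share, bor, alos, expected):
        p = profile(share=share, bor=bor, alos=alos)
        assert expected_admissions(beds, p) == pytest.approx(expected)

    def test_invalid_alos_rejected(self):
        with pytest.raises(ValueError):
            profile(alos=0.0)


class TestWeightedCost:
    def test_single_specialty_returns_its_cost(self):
        costs = default_specialty_costs()
        for s, c in PUBLISHED_COSTS.items():
            assert weighted_specialty_cost({s: 5.0}, costs) == pytest.approx(c)

    def test_equal_weights_ophthalmology_ent(self):
        costs = default_specialty_costs()
        got = weighted_specialty_cost(
            {"Ophthalmology": 10, "Ear Nose and Throat": 10}, costs
        )
        assert got == pytest.approx(11_985.5)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            weighted_specialty_cost({"Paediatrics": 0.0}, default_specialty_costs())

    @given(
        weights=st.lists(
            st.floats(0.0, 1e4, allow_nan=False), min_size=7, max_size=7
        ).filter(lambda w: sum(w) > 0)
    )
    @settings(deadline=None, max_examples=200)
    def test_any_weighting_brackets_published_overall(self, weights):
        """Weighted cost lies in [min, max] specialty cost, bracketing 12,156."""
        costs = default_specialty_costs()
        cases = dict(zip(SPECIALTIES, weights))
        got = weighted_specialty_cost(cases, costs)
        assert 9_867 - 1e-9 <= got <= 14_104 + 1e-9


class TestInpatientBudget:
    def test_zero_beds_is_zero(self):
        assert (
            inpatient_budget(
                0, default_specialty_profiles(), default_tariff_table(),
                default_specialty_costs(),
            )
            == 0.0
        )

    def test_non_pmjay_only_single_specialty(self):
        # 100 expected admissions priced entirely at the specialty cost
        p = profile(share=1.0, bor=100 * 4.0 / 365.0 / 100.0, alos=4.0, pmjay=0.0)
        # choose beds=100 so admissions = 100*bor*365/4 = 100
        got = inpatient_budget(
            100, [p], default_tariff_table(), default_specialty_costs()
        )
        assert got == pytest.approx(100 * 10_481, rel=1e-9)

    def test_pmjay_only_single_package(self):
        tariffs = TariffTable(
            entries={"X1": ("General Medicine", 5000.0)}, case_mix={"X1": 1.0}
        )
        p = profile(pmjay=1.0)
        beds = 50
        n = expected_admissions(beds, p)
        got = inpatient_budget(beds, [p], tariffs, default_specialty_costs())
        assert got == pytest.approx(n * 5000.0)

    def test_matches_per_admission_enumeration_oracle(self):
        """Brute-force oracle: price each admission individually and sum."""
        profiles = default_specialty_profiles()
        tariffs = default_tariff_table()
        costs = default_specialty_costs()
        beds = 40
        total = 0.0
        for p in profiles:
            adm = expected_admissions(beds, p)
            pm = adm * p.pmjay_share
            tariff_mean = tariffs.mean_cost(p.specialty)
            total += pm * tariff_mean
            total += (adm - pm) * costs.cost_per_admission[p.specialty]
        got = inpatient_budget(beds, profiles, tariffs, costs)
        assert got == pytest.approx(total, rel=1e-9)

    def test_homogeneity_in_beds(self):
        profiles = default_specialty_profiles()
        args = (default_tariff_table(), default_specialty_costs())
        one = inpatient_budget(150, profiles, *args)
        two = inpatient_budget(300, profiles, *args)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_monotone_in_tariffs_and_bor(self):
        profiles = default_specialty_profiles()
        tariffs = default_tariff_table()
        costs = default_specialty_costs()
        base = inpatient_budget(200, profiles, tariffs, costs)
        assert inpatient_budget(200, profiles, tariffs.scaled(1.5), costs) > base
        assert inpatient_budget(200, profiles, tariffs, costs.scaled(1.5)) > base
        hi_bor = [
            SpecialtyProfile(p.specialty, p.bed_share, p.alos, min(1.0, p.bor + 0.1), p.pmjay_share)
            for p in profiles
        ]
        assert inpatient_budget(200, hi_bor, tariffs, costs) > base

    def test_missing_specialty_raises_by_name(self):
        tariffs = TariffTable(
            entries={"X1": ("General Medicine", 5000.0)}, case_mix={"X1": 1.0}
        )
        p = profile(spec="Orthopedics", pmjay=1.0)
        with pytest.raises(KeyError, match="Orthopedics"):
            inpatient_budget(100, [p], tariffs, default_specialty_costs())

    def test_bed_shares_must_sum_to_one(self):
        p = profile(share=0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            inpatient_budget(100, [p], default_tariff_table(), default_specialty_costs())


def test_economic_cost_capital_rule():
    assert economic_cost(100.0, 250.0) == pytest.approx(150.0)
    assert economic_cost(0.0, 0.0) == 0.0


def test_tables_round_trip_csv(tmp_path):
    import pandas as pd

    costs = default_specialty_costs()
    p = tmp_path / "costs.csv"
    pd.DataFrame(
        {
            "specialty": list(costs.cost_per_admission),
            "cost_per_admission_inr": list(costs.cost_per_admission.values()),
        }
    ).to_csv(p, index=False)
    assert read_specialty_costs_csv(p).cost_per_admission == costs.cost_per_admission

    tariffs = default_tariff_table()
    q = tmp_path / "tariffs.csv"
    pd.DataFrame(
        [
            {"code": c, "specialty": s, "cost": cost, "share": tariffs.case_mix[c]}
            for c, (s, cost) in tariffs.entries.items()
        ]
    ).to_csv(q, index=False)
    back = read_tariff_csv(q)
    for spec in SPECIALTIES:
        assert back.mean_cost(spec) == pytest.approx(tariffs.mean_cost(spec))
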