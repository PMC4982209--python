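"""Micro-costing engine against a naive item-by-item oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from icuecon.costing import (
    assemble_breakdown,
    breakdown_table,
    cost_icu_stay,
    cost_post_hospital,
    cost_post_icu,
    daily_vent_cost,
    inflate,
)
from icuecon.cohort import CohortConfig, generate_cohort

from conftest import make_crf, make_patient, make_questionnaire


# ---------------------------------------------------------------------------
# naive oracle: day-by-day, item-by-item recomputation, no vectorisation

def oracle_icu_cost(crfs, costs):
    total = 0.0
    vent_daily = (costs.vent_machine_price / costs.vent_machine_life_years
                  + costs.vent_annual_maintenance) / costs.vent_utilisation_days_per_year
    ever_vent = False
    for _, row in crfs.iterrows():
        total += costs.cost_per_organ_day[int(row["organs_supported"])]
        if row["on_rrt"]:
            total += costs.rrt_cost
        total += int(row["xray_count"]) * costs.xray_cost
        if row["chest_drain"]:
            total += costs.chest_drain_cost
        for code, unit in costs.drug_costs.items():
            total += int(row[f"drug_{code}"]) * unit
        if row["on_ventilation"]:
            total += vent_daily
            ever_vent = True
    if ever_vent:
        total += costs.vent_circuit_cost
    return total


def oracle_post_icu(p, costs):
    stepdown = max(p["hospital_days"] - p["icu_days"] - p["readmission_days"], 0)
    hdu = min(p["hdu_days"], stepdown)
    total = (stepdown - hdu) * costs.stepdown_cost_per_day["ward"]
    total += hdu * costs.stepdown_cost_per_day["hdu"]
    total += p["readmission_days"] * costs.stepdown_cost_per_day["icu"]
    if p["discharged_to_other_hospital"]:
        total += costs.transfer_cost
    return total


def oracle_post_hospital(rows, costs):
    waves = {r["wave"] for _, r in rows.iterrows() if r["returned"]}
    if waves != {"6m", "12m"}:
        return None
    nhs = pc = 0.0
    for _, r in rows.iterrows():
        if not r["returned"]:
            continue
        nhs += r["gp_visits"] * costs.visit_costs["gp"]
        nhs += r["outpatient_visits"] * costs.visit_costs["outpatient"]
        nhs += r["community_visits"] * costs.visit_costs["community"]
        nhs += r["inpatient_days"] * costs.inpatient_cost_per_day
        if isinstance(r["aids_items"], str) and r["aids_items"]:
            nhs += sum(costs.aids_costs[i] for i in r["aids_items"].split(";"))
        pc += (r["travel_miles"] + r["carer_travel_miles"]) * costs.petrol_rate
        pc += r["lost_earnings"] + r["oop_expenses"] + r["carer_lost_earnings"]
    return nhs, pc


# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "price,life,maint,util,expected",
    [
        (0.0, 5.0, 0.0, 365.0, 0.0),
        (18250.0, 5.0, 0.0, 365.0, 10.0),
        (18250.0, 5.0, 365.0, 365.0, 11.0),
    ],
)
def test_daily_vent_cost(unit_costs, price, life, maint, util, expected):
    costs = dataclasses.replace(
        unit_costs, vent_machine_price=price, vent_machine_life_years=life,
        vent_annual_maintenance=maint,
    )
    assert daily_vent_cost(costs, util) == pytest.approx(expected)


def test_daily_vent_cost_rejects_nonpositive_utilisation(unit_costs):
    with pytest.raises(ValueError, match="utilisation"):
        daily_vent_cost(unit_costs, 0.0)


def test_icu_stay_zero_days(unit_costs):
    assert cost_icu_stay(make_crf(1, []), unit_costs) == 0.0


def test_icu_stay_sum_product(unit_costs):
    costs = dataclasses.replace(
        unit_costs, cost_per_organ_day={2: 1000.0}, xray_cost=50.0,
    )
    crf = make_crf(1, [{"organs_supported": 2}, {"organs_supported": 2, "xray_count": 1}])
    assert cost_icu_stay(crf, costs) == pytest.approx(2050.0)


def test_icu_stay_unknown_organ_count_named(unit_costs):
    costs = dataclasses.replace(unit_costs, cost_per_organ_day={0: 900.0, 1: 1200.0})
    crf = make_crf(1, [{"organs_supported": 5}])
    with pytest.raises(KeyError, match="5"):
        cost_icu_stay(crf, costs)


def test_icu_stay_mixed_days_matches_oracle(unit_costs):
    crf = make_crf(
        1,
        [
            {"organs_supported": 3, "on_ventilation": True, "drug_abx": 2},
            {"organs_supported": 2, "on_ventilation": True, "on_rrt": True, "xray_count": 2},
            {"organs_supported": 1, "chest_drain": True, "drug_sedative": 4},
        ],
    )
    assert cost_icu_stay(crf, unit_costs) == pytest.approx(oracle_icu_cost(crf, unit_costs))


def test_post_icu_cases(unit_costs):
    p = make_patient(icu_days=10, hospital_days=10)
    assert cost_post_icu(p, unit_costs) == 0.0

    p = make_patient(icu_days=5, hospital_days=15, hdu_days=0)
    assert cost_post_icu(p, unit_costs) == pytest.approx(10 * 297.0)

    p = make_patient(icu_days=5, hospital_days=20, hdu_days=4,
                     readmission_days=3, discharged_to_other_hospital=True)
    assert cost_post_icu(p, unit_costs, sae_events=("pneumothorax",)) == pytest.approx(
        oracle_post_icu(p, unit_costs) + unit_costs.sae_costs["pneumothorax"]
    )


def test_post_icu_unknown_care_level(unit_costs):
    costs = dataclasses.replace(unit_costs, stepdown_cost_per_day={"ward": 297.0})
    with pytest.raises(KeyError, match="hdu"):
        cost_post_icu(make_patient(), costs)


def test_post_icu_unknown_sae(unit_costs):
    with pytest.raises(KeyError, match="anaphylaxis"):
        cost_post_icu(make_patient(), unit_costs, sae_events=("anaphylaxis",))


def test_post_hospital_cases(unit_costs):
    both = pd.DataFrame([make_questionnaire(1, "6m"), make_questionnaire(1, "12m")])
    assert cost_post_hospital(both, unit_costs) == (0.0, 0.0)

    miles = pd.DataFrame([
        make_questionnaire(1, "6m", travel_miles=100.0),
        make_questionnaire(1, "12m"),
    ])
    nhs, pc = cost_post_hospital(miles, unit_costs)
    assert nhs == 0.0
    assert pc == pytest.approx(100.0 * 0.45)

    one_wave = pd.DataFrame([
        make_questionnaire(1, "6m"),
        make_questionnaire(1, "12m", returned=False),
    ])
    assert cost_post_hospital(one_wave, unit_costs) is None


def test_post_hospital_rejects_negative_amounts(unit_costs):
    q = pd.DataFrame([
        make_questionnaire(1, "6m", lost_earnings=-5.0),
        make_questionnaire(1, "12m"),
    ])
    with pytest.raises(ValueError, match="lost_earnings"):
        cost_post_hospital(q, unit_costs)


@pytest.mark.parametrize(
    "amount,year,expected",
    [(100.0, 2012, 100.0), (100.0, 2011, 100.0 * 277.4 / 270.3), (0.0, 2010, 0.0)],
)
def test_inflate(unit_costs, amount, year, expected):
    assert inflate(amount, year, unit_costs) == pytest.approx(expected)


def test_inflate_missing_year(unit_costs):
    with pytest.raises(KeyError, match="1999"):
        inflate(100.0, 1999, unit_costs)


def test_breakdown_for_icu_death(unit_costs):
    p = make_patient(death_day=3, alive_1yr=False, icu_days=5)
    crf = make_crf(1, [{"organs_supported": 2}] * 3)
    bd = assemble_breakdown(p, crf, pd.DataFrame(columns=["patient_id", "wave", "returned"]), unit_costs)
    assert bd["post_icu_hospital_cost"] == 0.0
    assert bd["post_hospital_nhs_cost"] == 0.0
    assert bd["total_societal_cost"] == pytest.approx(bd["icu_cost"])


def test_breakdown_survivor_matches_hand_total(unit_costs):
    p = make_patient(icu_days=2, vent_days=1, hospital_days=8, hdu_days=2)
    crf = make_crf(1, [
        {"organs_supported": 2, "on_ventilation": True},
        {"organs_supported": 1},
    ])
    q = pd.DataFrame([
        make_questionnaire(1, "6m", gp_visits=2, travel_miles=10.0),
        make_questionnaire(1, "12m", inpatient_days=3, lost_earnings=200.0),
    ])
    bd = assemble_breakdown(p, crf, q, unit_costs)
    # hand-summed totals from the bundled unit-cost file
    icu = 1454.0 + 1213.0 + 11.0 + 50.0
    post_icu = 2 * 741.0 + 4 * 297.0
    nhs = 2 * 45.0 + 3 * 300.0
    pc = 10.0 * 0.45 + 200.0
    assert bd["icu_cost"] == pytest.approx(icu)
    assert bd["post_icu_hospital_cost"] == pytest.approx(post_icu)
    assert bd["post_hospital_nhs_cost"] == pytest.approx(nhs)
    assert bd["patient_carer_cost"] == pytest.approx(pc)
    assert bd["total_societal_cost"] == pytest.approx(icu + post_icu + nhs + pc)


def test_survivor_with_missing_wave_has_missing_total(unit_costs):
    p = make_patient()
    q = pd.DataFrame([make_questionnaire(1, "6m")])
    bd = assemble_breakdown(p, make_crf(1, [{}] * 5), q, unit_costs)
    assert np.isnan(bd["post_hospital_nhs_cost"])
    assert np.isnan(bd["total_societal_cost"])


def test_engine_matches_oracle_on_50_patient_cohort(unit_costs):
    patients, crf, quests = generate_cohort(CohortConfig(n_patients=50, seed=13))
    table = breakdown_table(patients, crf, quests, unit_costs)
    for _, p in patients.iterrows():
        row = table[table["patient_id"] == p["id"]].iloc[0]
        my_crf = crf[crf["patient_id"] == p["id"]]
        my_q = quests[quests["patient_id"] == p["id"]]
        assert row["icu_cost"] == pytest.approx(oracle_icu_cost(my_crf, unit_costs))
        died_in_icu = pd.notna(p["death_day"]) and p["death_day"] <= p["icu_days"]
        expected_post = 0.0 if died_in_icu else oracle_post_icu(p, unit_costs)
        assert row["post_icu_hospital_cost"] == pytest.approx(expected_post)
        if p["alive_1yr"]:
            post = oracle_post_hospital(my_q, unit_costs)
            if post is None:
                assert np.isnan(row["post_hospital_nhs_cost"])
            else:
                assert row["post_hospital_nhs_cost"] == pytest.approx(post[0])
                assert row["patient_carer_cost"] == pytest.approx(post[1])
        else:
            assert row["post_hospital_nhs_cost"] == 0.0


def test_linearity_doubling_unit_costs_doubles_components(unit_costs):
    """Every unit-cost-driven component is exactly linear in the unit costs.
    Patient-reported monetary amounts (lost earnings, out-of-pocket) are
    pass-through, not unit-cost multiples, so they are zeroed here."""
    patients, crf, quests = generate_cohort(CohortConfig(n_patients=30, seed=17))
    quests = quests.copy()
    ret = quests["returned"].astype(bool)
    for col in ("lost_earnings", "oop_expenses", "carer_lost_earnings"):
        quests.loc[ret, col] = 0.0
    base = breakdown_table(patients, crf, quests, unit_costs)
    doubled = breakdown_table(patients, crf, quests, unit_costs.scaled(2.0))
    for col in ("icu_cost", "post_icu_hospital_cost", "hospital_cost",
                "post_hospital_nhs_cost", "patient_carer_cost", "total_societal_cost"):
        pd.testing.assert_series_equal(doubled[col], 2.0 * base[col], check_exact=False)


def test_additivity_and_nonnegativity(small_cohort, unit_costs):
    patients, crf, quests = small_cohort
    table = breakdown_table(patients, crf, quests, unit_costs)
    assert np.allclose(
        table["hospital_cost"], table["icu_cost"] + table["post_icu_hospital_cost"]
    )
    for col in ("icu_cost", "post_icu_hospital_cost",
                "post_hospital_nhs_cost", "patient_carer_cost"):
        vals = table[col].dropna()
        assert (vals >= 0).all()
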