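import numpy as np
import pandas as pd
import pytest

from icuecon import CohortConfig, generate_cohort, load_unit_costs, uk_tto_tariff


@pytest.fixture(scope="session")
def tariff():
    return uk_tto_tariff()


@pytest.fixture(scope="session")
def unit_costs():
    return load_unit_costs()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient synthetic cohort reused across read-only tests."""
    return generate_cohort(CohortConfig(n_patients=300, seed=42))


def make_crf(patient_id, days):
    """Hand-built daily CRF rows; ``days`` is a list of dicts of overrides."""
    defaults = {
        "organs_supported": 2, "on_ventilation": False, "on_rrt": False,
        "xray_count": 0, "chest_drain": False,
        "drug_abx": 0, "drug_sedative": 0, "drug_relaxant": 0,
    }
    rows = []
    for i, overrides in enumerate(days, start=1):
        row = {"patient_id": patient_id, "day_index": i, **defaults, **overrides}
        rows.append(row)
    return pd.DataFrame(rows)


def make_patient(**overrides):
    base = {
        "id": 1, "arm": "conventional", "age": 55.0, "sex": "male",
        "apache2": 20, "pf_ratio": 15.0, "prime_condition": "pneumonia",
        "surgery_admission": False, "icu_days": 5, "vent_days": 3,
        "hdu_days": 0, "hospital_days": 10, "death_day": pd.NA,
        "alive_1yr": True, "discharged_to_other_hospital": False,
        "readmission_days": 0,
    }
    base.update(overrides)
    return base


def make_questionnaire(patient_id, wave, returned=True, **overrides):
    base = {
        "patient_id": patient_id, "wave": wave, "returned": returned,
        "eq5d_state": "11111", "gp_visits": 0, "outpatient_visits": 0,
        "community_visits": 0, "inpatient_days": 0, "aids_items": "",
        "travel_miles": 0.0, "lost_earnings": 0.0, "oop_expenses": 0.0,
        "carer_travel_miles": 0.0, "carer_lost_earnings": 0.0,
    }
    if not returned:
        for k in base:
            if k not in ("patient_id", "wave", "returned"):
                base[k] = np.nan
    base.update(overrides)
    return base
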