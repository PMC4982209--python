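"""Bottom-up micro-costing of the care pathways of an ICU admission.

Each patient's resource volumes are multiplied by unit costs and summed,
pathway by pathway:

* initial ICU stay — daily case-report rows priced per organ-support day
  plus renal replacement, imaging, chest drains, drugs and the daily
  ventilation cost (machine amortised straight-line over its service life
  plus annual maintenance, spread over assumed utilisation days, plus a
  one-off single-use circuit per ventilated patient);
* post-ICU hospital stay — step-down days at ward/high-dependency rates,
  ICU readmission days at the critical-care rate, an emergency transfer
  fee when the patient left to another hospital, and itemised serious
  adverse events;
* post-hospital year — NHS visits, inpatient days and aids/equipment from
  the follow-up questionnaires, and the societal component (patient and
  carer travel at a petrol-mile rate, lost earnings, out-of-pocket items).
  The post-hospital components are only defined for survivors who
  returned both the 6- and the 12-month questionnaire; otherwise they are
  missing and left to the imputation stage.

All amounts are expressed in base-year GBP; `inflate` restates amounts
from another price year using a hospital pay-and-prices index.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


@dataclass
class UnitCostTable:
    cost_per_organ_day: dict[int, float]
    xray_cost: float
    chest_drain_cost: float
    rrt_cost: float
    drug_costs: dict[str, float]
    vent_machine_price: float
    vent_machine_life_years: float
    vent_annual_maintenance: float
    vent_circuit_cost: float
    stepdown_cost_per_day: dict[str, float]
    transfer_cost: float
    sae_costs: dict[str, float]
    visit_costs: dict[str, float]
    inpatient_cost_per_day: float
    aids_costs: dict[str, float]
    petrol_rate: float
    hchs_index: dict[int, float]
    base_year: int = 2012
    vent_utilisation_days_per_year: float = 365.0

    def __post_init__(self) -> None:
        scalars = [self.xray_cost, self.chest_drain_cost, self.rrt_cost,
                   self.vent_machine_price, self.vent_annual_maintenance,
                   self.vent_circuit_cost, self.transfer_cost,
                   self.inpatient_cost_per_day, self.petrol_rate]
        maps = [self.cost_per_organ_day, self.drug_costs, self.stepdown_cost_per_day,
                self.sae_costs, self.visit_costs, self.aids_costs]
        if any(v < 0 for v in scalars) or any(v < 0 for m in maps for v in m.values()):
            raise ValueError("unit costs must be non-negative")
        if self.vent_machine_life_years <= 0:
            raise ValueError("vent_machine_life_years must be > 0")
        if self.base_year not in self.hchs_index:
            raise ValueError(f"hchs_index must contain the base year {self.base_year}")

    def scaled(self, factor: float) -> "UnitCostTable":
        """A copy with every unit cost multiplied by ``factor`` (index untouched)."""
        return UnitCostTable(
            cost_per_organ_day={k: v * factor for k, v in self.cost_per_organ_day.items()},
            xray_cost=self.xray_cost * factor,
            chest_drain_cost=self.chest_drain_cost * factor,
            rrt_cost=self.rrt_cost * factor,
            drug_costs={k: v * factor for k, v in self.drug_costs.items()},
            vent_machine_price=self.vent_machine_price * factor,
            vent_machine_life_years=self.vent_machine_life_years,
            vent_annual_maintenance=self.vent_annual_maintenance * factor,
            vent_circuit_cost=self.vent_circuit_cost * factor,
            stepdown_cost_per_day={k: v * factor for k, v in self.stepdown_cost_per_day.items()},
            transfer_cost=self.transfer_cost * factor,
            sae_costs={k: v * factor for k, v in self.sae_costs.items()},
            visit_costs={k: v * factor for k, v in self.visit_costs.items()},
            inpatient_cost_per_day=self.inpatient_cost_per_day * factor,
            aids_costs={k: v * factor for k, v in self.aids_costs.items()},
            petrol_rate=self.petrol_rate * factor,
            hchs_index=dict(self.hchs_index),
            base_year=self.base_year,
            vent_utilisation_days_per_year=self.vent_utilisation_days_per_year,
        )


def load_unit_costs(path: str | Path | None = None) -> UnitCostTable:
    """Load a unit-cost table from YAML (bundled illustrative table by default)."""
    if path is None:
        text = importlib.resources.files("icuecon.data").joinpath("unit_costs.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"unit-cost file not found: {path}")
        text = path.read_text()
    raw = yaml.safe_load(text)
    return UnitCostTable(
        cost_per_organ_day={int(k): float(v) for k, v in raw["cost_per_organ_day"].items()},
        xray_cost=float(raw["xray_cost"]),
        chest_drain_cost=float(raw["chest_drain_cost"]),
        rrt_cost=float(raw["rrt_cost"]),
        drug_costs={str(k): float(v) for k, v in raw["drug_costs"].items()},
        vent_machine_price=float(raw["vent_machine_price"]),
        vent_machine_life_years=float(raw["vent_machine_life_years"]),
        vent_annual_maintenance=float(raw["vent_annual_maintenance"]),
        vent_circuit_cost=float(raw["vent_circuit_cost"]),
        stepdown_cost_per_day={str(k): float(v) for k, v in raw["stepdown_cost_per_day"].items()},
        transfer_cost=float(raw["transfer_cost"]),
        sae_costs={str(k): float(v) for k, v in raw["sae_costs"].items()},
        visit_costs={str(k): float(v) for k, v in raw["visit_costs"].items()},
        inpatient_cost_per_day=float(raw["inpatient_cost_per_day"]),
        aids_costs={str(k): float(v) for k, v in raw["aids_costs"].items()},
        petrol_rate=float(raw["petrol_rate"]),
        hchs_index={int(k): float(v) for k, v in raw["hchs_index"].items()},
        base_year=int(raw["base_year"]),
        vent_utilisation_days_per_year=float(raw.get("vent_utilisation_days_per_year", 365.0)),
    )


def daily_vent_cost(costs: UnitCostTable, assumed_daily_utilisation: float | None = None) -> float:
    """Fixed daily ventilation cost: straight-line machine amortisation plus
    annual maintenance spread over the machine's utilisation days per year.
    The per-patient single-use circuit is charged once elsewhere."""
    util = assumed_daily_utilisation
    if util is None:
        util = costs.vent_utilisation_days_per_year
    if util <= 0:
        raise ValueError(f"assumed daily utilisation must be > 0, got {util}")
    annual = costs.vent_machine_price / costs.vent_machine_life_years + costs.vent_annual_maintenance
    return annual / util


def cost_icu_stay(crfs: pd.DataFrame, costs: UnitCostTable) -> float:
    """Total cost of one patient's initial ICU stay from daily CRF rows."""
    if crfs.empty:
        return 0.0
    if crfs["patient_id"].nunique() > 1:
        raise ValueError("cost_icu_stay expects CRF rows for a single patient")
    vent_daily = daily_vent_cost(costs)
    drug_cols = [c for c in crfs.columns if c.startswith("drug_")]
    for code in (c.removeprefix("drug_") for c in drug_cols):
        if code not in costs.drug_costs:
            raise KeyError(f"no unit cost configured for drug {code!r}")
    organs = crfs["organs_supported"].astype(int)
    unknown = set(organs.unique()) - set(costs.cost_per_organ_day)
    if unknown:
        raise KeyError(
            f"no daily rate configured for organ-support count {min(unknown)}"
        )
    total = float(organs.map(costs.cost_per_organ_day).sum())
    total += float(crfs["on_rrt"].astype(bool).sum()) * costs.rrt_cost
    total += float(crfs["xray_count"].astype(int).sum()) * costs.xray_cost
    total += float(crfs["chest_drain"].astype(bool).sum()) * costs.chest_drain_cost
    for col in drug_cols:
        total += float(crfs[col].astype(int).sum()) * costs.drug_costs[col.removeprefix("drug_")]
    on_vent = crfs["on_ventilation"].astype(bool)
    total += float(on_vent.sum()) * vent_daily
    if on_vent.any():
        total += costs.vent_circuit_cost
    return float(total)


def cost_post_icu(
    patient: Mapping, costs: UnitCostTable, sae_events: Sequence[str] = ()
) -> float:
    """Cost of the hospital stay after first ICU discharge for an ICU survivor:
    step-down days at their care-level rates, readmission days at the
    critical-care rate, an emergency transfer if discharged to another
    hospital, plus itemised serious adverse events."""
    stepdown = int(patient["hospital_days"]) - int(patient["icu_days"]) - int(
        patient["readmission_days"]
    )
    stepdown = max(stepdown, 0)
    hdu = min(int(patient.get("hdu_days", 0)), stepdown)
    ward = stepdown - hdu
    for level in ("ward", "hdu", "icu"):
        if level not in costs.stepdown_cost_per_day:
            raise KeyError(f"no daily rate configured for care level {level!r}")
    total = ward * costs.stepdown_cost_per_day["ward"]
    total += hdu * costs.stepdown_cost_per_day["hdu"]
    total += int(patient["readmission_days"]) * costs.stepdown_cost_per_day["icu"]
    if bool(patient.get("discharged_to_other_hospital", False)):
        total += costs.transfer_cost
    for event in sae_events:
        if event not in costs.sae_costs:
            raise KeyError(f"no unit cost configured for serious adverse event {event!r}")
        total += costs.sae_costs[event]
    return float(total)


def _wave_nhs(row: Mapping, costs: UnitCostTable) -> float:
    total = int(row["gp_visits"]) * costs.visit_costs["gp"]
    total += int(row["outpatient_visits"]) * costs.visit_costs["outpatient"]
    total += int(row["community_visits"]) * costs.visit_costs["community"]
    total += int(row["inpatient_days"]) * costs.inpatient_cost_per_day
    items = row.get("aids_items")
    if isinstance(items, str) and items:
        for item in items.split(";"):
            if item not in costs.aids_costs:
                raise KeyError(f"no unit cost configured for aids item {item!r}")
            total += costs.aids_costs[item]
    return total


def _wave_patient_carer(row: Mapping, costs: UnitCostTable) -> float:
    amounts = {k: float(row[k]) for k in
               ("travel_miles", "lost_earnings", "oop_expenses",
                "carer_travel_miles", "carer_lost_earnings")}
    for k, v in amounts.items():
        if v < 0:
            raise ValueError(f"negative reported amount in {k!r}: {v}")
    miles = amounts["travel_miles"] + amounts["carer_travel_miles"]
    return (miles * costs.petrol_rate + amounts["lost_earnings"]
            + amounts["oop_expenses"] + amounts["carer_lost_earnings"])


def cost_post_hospital(
    questionnaires: pd.DataFrame, costs: UnitCostTable
) -> tuple[float, float] | None:
    """Post-hospital (NHS, patient/carer) costs for one survivor over the year.

    Returns None (missing) unless both the 6- and 12-month questionnaires
    were returned — the two waves jointly cover the follow-up year, so a
    single wave cannot support an annual total.
    """
    if questionnaires.empty or questionnaires["patient_id"].nunique() > 1:
        if questionnaires.empty:
            return None
        raise ValueError("cost_post_hospital expects questionnaires for one patient")
    ret = questionnaires[questionnaires["returned"].astype(bool)]
    if set(ret["wave"]) != {"6m", "12m"}:
        return None
    nhs = sum(_wave_nhs(row, costs) for _, row in ret.iterrows())
    pc = sum(_wave_patient_carer(row, costs) for _, row in ret.iterrows())
    return float(nhs), float(pc)


def inflate(amount: float, from_year: int, costs: UnitCostTable) -> float:
    """Restate ``amount`` from ``from_year`` prices into base-year prices
    using the configured pay-and-prices index."""
    for year in (from_year, costs.base_year):
        if year not in costs.hchs_index:
            raise KeyError(f"year {year} missing from the inflation index")
    return amount * costs.hchs_index[costs.base_year] / costs.hchs_index[from_year]


def assemble_breakdown(
    patient: Mapping,
    crfs: pd.DataFrame,
    questionnaires: pd.DataFrame,
    costs: UnitCostTable,
    sae_events: Sequence[str] = (),
) -> dict:
    """One patient's cost breakdown across care pathways, base-year GBP.

    Patients who died in ICU accrue no post-ICU cost; patients dead within
    the year accrue no post-hospital cost (zero, not missing). For one-year
    survivors the post-hospital components are missing (NaN) unless both
    follow-up questionnaires were returned; the societal total is only
    formed when every component is present.
    """
    try:
        icu_cost = cost_icu_stay(crfs, costs)
    except (KeyError, ValueError) as exc:
        raise type(exc)(f"ICU pathway, patient {patient['id']}: {exc}") from exc

    death_day = patient.get("death_day")
    died_in_icu = pd.notna(death_day) and int(death_day) <= int(patient["icu_days"])
    if died_in_icu:
        post_icu = 0.0
    else:
        try:
            post_icu = cost_post_icu(patient, costs, sae_events)
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"post-ICU pathway, patient {patient['id']}: {exc}") from exc

    alive = bool(patient["alive_1yr"])
    if not alive:
        nhs, pc = 0.0, 0.0
    else:
        try:
            post = cost_post_hospital(questionnaires, costs)
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"post-hospital pathway, patient {patient['id']}: {exc}") from exc
        nhs, pc = (np.nan, np.nan) if post is None else post

    total = icu_cost + post_icu + nhs + pc  # NaN propagates when components missing
    return {
        "patient_id": int(patient["id"]),
        "icu_cost": icu_cost,
        "post_icu_hospital_cost": post_icu,
        "hospital_cost": icu_cost + post_icu,
        "post_hospital_nhs_cost": nhs,
        "patient_carer_cost": pc,
        "total_societal_cost": total,
    }


def breakdown_table(
    patients: pd.DataFrame,
    crfs: pd.DataFrame,
    questionnaires: pd.DataFrame,
    costs: UnitCostTable,
) -> pd.DataFrame:
    """Cost breakdowns for a whole cohort, one row per patient."""
    crf_groups = dict(tuple(crfs.groupby("patient_id"))) if len(crfs) else {}
    q_groups = dict(tuple(questionnaires.groupby("patient_id"))) if len(questionnaires) else {}
    empty_crf = crfs.iloc[0:0]
    empty_q = questionnaires.iloc[0:0]
    rows = [
        assemble_breakdown(
            patient,
            crf_groups.get(patient["id"], empty_crf),
            q_groups.get(patient["id"], empty_q),
            costs,
        )
        for _, patient in patients.iterrows()
    ]
    return pd.DataFrame(rows)
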