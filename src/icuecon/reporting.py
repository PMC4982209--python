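"""Summary surfaces of the one-year economic evaluation.

Mortality and questionnaire-response rates, pathway and subgroup cost
tables (mean, normal 95 % CI, median, quartiles), baseline comparison of
survivors and non-survivors (Welch t / chi-squared, uncorrected), cost
per one-year survivor, the incremental cost-effectiveness ratio between
ventilation strategies, and `run_pipeline`, which chains every stage:

    simulate -> score utilities -> cost pathways -> impute -> QALY -> report
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cohort import DAYS_6M, DAYS_12M, CohortConfig, generate_cohort, write_cohort
from .costing import UnitCostTable, breakdown_table, load_unit_costs
from .eq5d import mean_wave_utility, compare_to_reference, eq5d_utility, uk_tto_tariff
from .imputation import ImputationSpec, impute_costs, pooled_column_mean
from .survival import quality_adjusted_survival

GROUP_CUTPOINTS = {"age": 65.0, "apache": 26.0, "pf": 15.0, "icu_los": 15.0}


@dataclass
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    status: str  # "ratio", "dominant", "dominated" or "undefined"


def mortality_rates(patients: pd.DataFrame) -> dict:
    """In-hospital and one-year mortality as percentages (1 dp) with counts.

    In-hospital deaths are those at or before hospital discharge (ICU
    deaths plus post-ICU hospital deaths); the one-year rate adds deaths
    after discharge up to day 365.
    """
    death = patients["death_day"]
    alive = patients["alive_1yr"].astype(bool)
    bad = patients.loc[(death.notna() & (death <= 365)) == alive, "id"]
    if len(bad):
        raise ValueError(
            f"inconsistent vital-status fields for patient id {int(bad.iloc[0])}"
        )
    n = len(patients)
    died = death.notna() & (death <= 365)
    icu_deaths = int((died & (death <= patients["icu_days"])).sum())
    hosp_deaths = int(
        (died & (death > patients["icu_days"]) & (death <= patients["hospital_days"])).sum()
    )
    later_deaths = int((died & (death > patients["hospital_days"])).sum())
    in_hosp = round(100.0 * (icu_deaths + hosp_deaths) / n, 1)
    one_year = round(100.0 * (icu_deaths + hosp_deaths + later_deaths) / n, 1)
    return {
        "in_hospital_pct": in_hosp,
        "one_year_pct": one_year,
        "counts": {
            "randomised": n,
            "icu_deaths": icu_deaths,
            "post_icu_hospital_deaths": hosp_deaths,
            "post_discharge_deaths": later_deaths,
        },
    }


def response_rate(questionnaires: pd.DataFrame, patients: pd.DataFrame) -> dict:
    """Returned questionnaires per eligible survivor at each wave, % to 1 dp."""
    death = patients["death_day"].fillna(10**6)
    out = {}
    for wave, horizon in (("6m", DAYS_6M), ("12m", DAYS_12M)):
        denom = int((death > horizon).sum())
        if denom == 0:
            raise ValueError(f"no surviving patients at wave {wave}")
        ret = questionnaires[
            (questionnaires["wave"] == wave) & questionnaires["returned"].astype(bool)
        ]
        out[wave] = round(100.0 * len(ret) / denom, 1)
    return out


def _summary_row(label: str, x: np.ndarray) -> dict:
    n = len(x)
    mean = float(np.mean(x))
    if n >= 2:
        se = float(np.std(x, ddof=1) / np.sqrt(n))
        ci = (mean - 1.96 * se, mean + 1.96 * se)
        defined = True
    else:
        ci = (np.nan, np.nan)
        defined = False
    q25, med, q75 = (float(q) for q in np.percentile(x, [25, 50, 75]))
    return {
        "label": label, "n": n, "mean": mean,
        "ci_low": ci[0], "ci_high": ci[1], "ci_defined": defined,
        "median": med, "q25": q25, "q75": q75,
    }


def summarise_costs(
    data: pd.DataFrame,
    grouping: str = "none",
    value_col: str = "total_societal_cost",
    apache_cut: float = 26.0,
) -> pd.DataFrame:
    """Per-group summary rows of a cost column.

    ``data`` is the cost-breakdown table joined to the patient table.
    Groupings use the study cut-points: age 65 years, APACHE II 26 (22
    available via ``apache_cut``), PaO2:FiO2 15 kPa, ICU stay 15 days.
    """
    x = data[value_col].to_numpy(float)
    if np.isnan(x).any():
        raise ValueError(f"{value_col!r} contains missing values; impute first")
    if grouping == "none":
        groups = pd.Series("all", index=data.index)
    elif grouping == "age":
        groups = np.where(data["age"] < GROUP_CUTPOINTS["age"], "age <65", "age >=65")
    elif grouping == "apache":
        groups = np.where(data["apache2"] < apache_cut,
                          f"APACHE II <{apache_cut:g}", f"APACHE II >={apache_cut:g}")
    elif grouping == "pf":
        groups = np.where(data["pf_ratio"] < GROUP_CUTPOINTS["pf"],
                          "PF <15 kPa", "PF >=15 kPa")
    elif grouping == "icu_los":
        groups = np.where(data["icu_days"] <= GROUP_CUTPOINTS["icu_los"],
                          "ICU los <=15 d", "ICU los >15 d")
    elif grouping in ("sex", "arm", "prime_condition", "surgery"):
        col = "surgery_admission" if grouping == "surgery" else grouping
        groups = data[col].astype(str)
    else:
        raise KeyError(f"unknown grouping {grouping!r}")
    groups = pd.Series(groups, index=data.index)
    rows = [_summary_row(label, x[(groups == label).to_numpy()])
            for label in sorted(groups.unique())]
    return pd.DataFrame(rows)


def cost_per_survivor(breakdowns: pd.DataFrame, patients: pd.DataFrame) -> float:
    """Total societal cost of the whole cohort divided by the number of
    patients alive one year post-randomisation."""
    totals = breakdowns["total_societal_cost"].to_numpy(float)
    if np.isnan(totals).any():
        raise ValueError("total costs contain missing values; impute first")
    survivors = int(patients["alive_1yr"].astype(bool).sum())
    if survivors == 0:
        raise ValueError("no one-year survivors; cost per survivor is undefined")
    return float(totals.sum() / survivors)


def icer(costs_by_arm: dict, qalys_by_arm: dict) -> ICERResult:
    """Incremental cost-effectiveness ratio of hfov vs conventional, with
    dominance handling when the signs make the ratio misleading."""
    for d in (costs_by_arm, qalys_by_arm):
        if set(d) != {"conventional", "hfov"}:
            raise KeyError("expected exactly the arms 'conventional' and 'hfov'")
    dc = float(costs_by_arm["hfov"] - costs_by_arm["conventional"])
    dq = float(qalys_by_arm["hfov"] - qalys_by_arm["conventional"])
    if dq == 0:
        return ICERResult(dc, dq, None, "undefined")
    ratio = dc / dq
    if dq > 0 and dc <= 0:
        status = "dominant"
    elif dq < 0 and dc >= 0:
        status = "dominated"
    else:
        status = "ratio"
    return ICERResult(dc, dq, ratio, status)


def baseline_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics of one-year survivors vs non-survivors:
    Welch t for continuous variables, chi-squared for categorical ones,
    with no multiple-testing correction."""
    alive = patients["alive_1yr"].astype(bool)
    rows = []
    continuous = ["age", "apache2", "pf_ratio", "icu_days", "hospital_days"]
    for col in continuous:
        a = patients.loc[alive, col].to_numpy(float)
        b = patients.loc[~alive, col].to_numpy(float)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"characteristic": col, "survivors": a.mean(),
                     "non_survivors": b.mean(), "stat": float(t), "p": float(p)})
    categorical = {
        "female": patients["sex"] == "female",
        "pneumonia": patients["prime_condition"] == "pneumonia",
        "surgery_admission": patients["surgery_admission"].astype(bool),
    }
    for name, flag in categorical.items():
        table = pd.crosstab(flag, alive)
        if table.shape == (2, 2):
            chi2, p, _, _ = stats.chi2_contingency(table)
        else:
            chi2, p = np.nan, np.nan
        rows.append({"characteristic": name,
                     "survivors": float(flag[alive].mean()),
                     "non_survivors": float(flag[~alive].mean()),
                     "stat": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)


def _survival_inputs(patients: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    death = patients["death_day"]
    died = (death.notna() & (death <= 365)).to_numpy()
    times = np.where(died, death.fillna(365).to_numpy(float), 365.0)
    return times, died


def run_pipeline(
    config: CohortConfig | None = None,
    unit_costs: UnitCostTable | str | Path | None = None,
    outdir: str | Path | None = None,
    n_boot: int = 1000,
    groupings: tuple[str, ...] = ("none", "age", "apache", "arm"),
) -> dict:
    """Run the full evaluation on a synthetic cohort and collect the report.

    Stages: simulate the cohort; score EQ-5D utilities; micro-cost the
    pathways; multiply impute missing post-hospital costs among one-year
    survivors; estimate partitioned-KM quality-adjusted survival; assemble
    rates, cost tables, cost per survivor and the between-arm ICER.
    Deterministic for a fixed ``config.seed``. If ``outdir`` is given the
    cohort CSVs, tables, a JSON summary and a run log are written there.
    """
    cfg = config or CohortConfig()
    if unit_costs is None or isinstance(unit_costs, (str, Path)):
        costs = load_unit_costs(unit_costs)
    else:
        costs = unit_costs

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    patients, crf, quests = stage("simulate", generate_cohort, cfg)

    u6, ci6, n6 = stage("score", mean_wave_utility, quests, "6m")
    u12, ci12, n12 = stage("score", mean_wave_utility, quests, "12m")

    breakdowns = stage("cost", breakdown_table, patients, crf, quests, costs)

    merged = breakdowns.merge(patients, left_on="patient_id", right_on="id")
    spec = ImputationSpec(seed=cfg.seed)
    cost_cols = ["post_hospital_nhs_cost", "patient_carer_cost"]
    completed = stage("impute", impute_costs, merged, cost_cols, spec)
    for df in completed:
        df["total_societal_cost"] = (
            df["hospital_cost"] + df["post_hospital_nhs_cost"] + df["patient_carer_cost"]
        )
    pooled_total = pooled_column_mean(completed, "total_societal_cost")
    cps = float(np.mean([cost_per_survivor(df, patients) for df in completed]))

    times, died = _survival_inputs(patients)
    vent_mean = float(patients["vent_days"].mean())
    qaly = stage(
        "qaly", quality_adjusted_survival,
        times, died, vent_mean, u6, u12, n_boot=n_boot, seed=cfg.seed,
    )

    arm_costs, arm_qalys = {}, {}
    for arm in ("conventional", "hfov"):
        in_arm = (merged["arm"] == arm).to_numpy()
        arm_costs[arm] = float(
            np.mean([df.loc[in_arm, "total_societal_cost"].mean() for df in completed])
        )
        sel = patients["arm"] == arm
        t_a, d_a = _survival_inputs(patients[sel])
        v_a = float(patients.loc[sel, "vent_days"].mean())
        arm_qalys[arm] = quality_adjusted_survival(
            t_a, d_a, v_a, u6, u12, n_boot=0
        ).qaly
    icer_res = stage("report", icer, arm_costs, arm_qalys)

    first = completed[0]
    subgroup_tables = {
        g: summarise_costs(first, g) for g in groupings
    }
    bundle = {
        "config": cfg,
        "patients": patients,
        "daily_crf": crf,
        "questionnaires": quests,
        "breakdowns": breakdowns,
        "completed_datasets": completed,
        "utilities": {"6m": (u6, ci6, n6), "12m": (u12, ci12, n12)},
        "qaly": qaly,
        "mortality": mortality_rates(patients),
        "response": response_rate(quests, patients),
        "pooled_total_cost": pooled_total,
        "cost_per_survivor": cps,
        "arm_costs": arm_costs,
        "arm_qalys": arm_qalys,
        "icer": icer_res,
        "baseline": baseline_table(patients),
        "subgroup_tables": subgroup_tables,
        "run_log": {
            "seed": cfg.seed,
            "n_patients": cfg.n_patients,
            "icuecon_version": __version__,
            "python": platform.python_version(),
        },
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(
        (bundle["patients"], bundle["daily_crf"], bundle["questionnaires"]), outdir
    )
    bundle["breakdowns"].to_csv(outdir / "cost_breakdown.csv", index=False)
    bundle["baseline"].to_csv(outdir / "baseline_table.csv", index=False)
    for g, table in bundle["subgroup_tables"].items():
        table.to_csv(outdir / f"costs_by_{g}.csv", index=False)
    qaly = bundle["qaly"]
    pooled = bundle["pooled_total_cost"]
    summary = {
        "mortality": bundle["mortality"],
        "response": bundle["response"],
        "utilities": {
            w: {"mean": v[0], "ci": list(v[1]), "n": v[2]}
            for w, v in bundle["utilities"].items()
        },
        "qaly": {
            "qaly": qaly.qaly,
            "ci": list(qaly.ci) if qaly.ci else None,
            "period_bounds": list(qaly.period_bounds),
            "period_utilities": list(qaly.period_utilities),
            "period_areas": list(qaly.period_areas),
        },
        "pooled_total_cost": {
            "mean": pooled.point, "ci": list(pooled.ci), "total_var": pooled.total_var,
        },
        "cost_per_survivor": bundle["cost_per_survivor"],
        "arm_costs": bundle["arm_costs"],
        "arm_qalys": bundle["arm_qalys"],
        "icer": dataclasses.asdict(bundle["icer"]),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    log = bundle["run_log"]
    (outdir / "run_log.txt").write_text(
        "".join(f"{k}: {v}\n" for k, v in log.items())
    )
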