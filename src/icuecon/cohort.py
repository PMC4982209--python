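"""Synthetic patient-level trial data for a one-year ICU/ARDS economic study.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be exercised without access to
patient-level trial data: baseline covariates with the published cohort
moments, a two-component survival mixture concentrated in the first month,
moment-matched lognormal lengths of stay, daily ICU case-report rows,
and 6-/12-month follow-up questionnaires with EQ-5D states calibrated to
the published survivor means and a missing-at-random non-response
mechanism driven by age and illness severity.

Three tables are produced (and round-tripped through CSV):

``patients``        one row per randomised patient
``daily_crf``       one row per patient per ICU day (resource-use vector)
``questionnaires``  one row per eligible survivor per follow-up wave
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .eq5d import sample_states_with_mean, uk_tto_tariff

DAYS_6M = 182  # questionnaire eligibility horizons, days post-randomisation
DAYS_12M = 365

# share of post-ICU step-down time spent at high-dependency level; with the
# bundled rates this puts the post-ICU daily cost near the published ~700
# GBP/day and the ICU share of hospital cost near the published ~70-75 %
HDU_FRACTION = 0.75


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the source trial cohort's published summary moments:
    795 randomised patients, mean age 55.4 (SD 16.8) years, 37.7 % female,
    APACHE II 21.8 (6.1), PaO2:FiO2 15.1 (5.0) kPa, ICU stay 17.0 (16.5)
    days, hospital stay 33.6 days, 51.2 % one-year mortality concentrated
    in the first 30 days, survivor EQ-5D means 0.5622 / 0.5831 at 6 / 12
    months, and 12-month questionnaire non-response of 47.2 % that rises
    with age and APACHE II (missing at random).
    """

    n_patients: int = 795
    allocation_ratio: float = 0.5
    age_mean: float = 55.4
    age_sd: float = 16.8
    prop_female: float = 0.377
    apache_mean: float = 21.8
    apache_sd: float = 6.1
    pf_mean: float = 15.1
    pf_sd: float = 5.0
    icu_los_mean: float = 17.0
    icu_los_sd: float = 16.5
    hosp_los_mean: float = 33.6
    one_year_mortality: float = 0.512
    early_death_fraction: float = 0.9
    vent_days_mean: float = 11.0
    eq5d_mean_6m: float = 0.5622
    eq5d_mean_12m: float = 0.5831
    eq5d_latent_sd: float = 0.37
    nonresponse_6m: float = 0.411
    nonresponse_12m: float = 0.472
    nonresponse_mar_strength: float = 0.3
    seed: int = 1

    def validate(self) -> None:
        probs = (
            "allocation_ratio prop_female one_year_mortality early_death_fraction "
            "nonresponse_6m nonresponse_12m"
        ).split()
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("age_sd", "apache_sd", "pf_sd", "icu_los_sd", "eq5d_latent_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_patients < 2:
            raise ValueError(f"n_patients must be >= 2, got {self.n_patients}")
        for name in ("age_mean", "apache_mean", "pf_mean", "icu_los_mean",
                     "hosp_los_mean", "vent_days_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


# ---------------------------------------------------------------------------
# table schemas (shared by the generator and the CSV reader)

PATIENT_SCHEMA = {
    "id": "int64",
    "arm": "str",
    "age": "float64",
    "sex": "str",
    "apache2": "int64",
    "pf_ratio": "float64",
    "prime_condition": "str",
    "surgery_admission": "boolean",
    "icu_days": "int64",
    "vent_days": "int64",
    "hdu_days": "int64",
    "hospital_days": "int64",
    "death_day": "Int64",
    "alive_1yr": "boolean",
    "discharged_to_other_hospital": "boolean",
    "readmission_days": "int64",
}

CRF_SCHEMA = {
    "patient_id": "int64",
    "day_index": "int64",
    "organs_supported": "int64",
    "on_ventilation": "boolean",
    "on_rrt": "boolean",
    "xray_count": "int64",
    "chest_drain": "boolean",
    "drug_abx": "int64",
    "drug_sedative": "int64",
    "drug_relaxant": "int64",
}

QUESTIONNAIRE_SCHEMA = {
    "patient_id": "int64",
    "wave": "str",
    "returned": "boolean",
    "eq5d_state": "str",
    "gp_visits": "Int64",
    "outpatient_visits": "Int64",
    "community_visits": "Int64",
    "inpatient_days": "Int64",
    "aids_items": "str",
    "travel_miles": "float64",
    "lost_earnings": "float64",
    "oop_expenses": "float64",
    "carer_travel_miles": "float64",
    "carer_lost_earnings": "float64",
}

_FILES = {
    "patients": ("patients.csv", PATIENT_SCHEMA),
    "daily_crf": ("daily_crf.csv", CRF_SCHEMA),
    "questionnaires": ("questionnaires.csv", QUESTIONNAIRE_SCHEMA),
}


def _cast(df: pd.DataFrame, schema: dict[str, str]) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col, dtype in schema.items():
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        s = df[col]
        if dtype == "boolean":
            s = s.map(
                {True: True, False: False, "True": True, "False": False},
                na_action="ignore",
            ).astype("boolean")
        elif dtype == "str":
            s = s.astype(object).where(~pd.isna(s), np.nan)
        else:
            s = s.astype(dtype)
        out[col] = s
    return out


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws moment-matched to an arithmetic mean and SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


# ---------------------------------------------------------------------------
# generation

def _generate_patients(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    arm = np.where(rng.random(n) < cfg.allocation_ratio, "hfov", "conventional")
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 16.0, 100.0)
    sex = np.where(rng.random(n) < cfg.prop_female, "female", "male")
    apache2 = np.clip(np.rint(rng.normal(cfg.apache_mean, cfg.apache_sd, n)), 0, 71)
    pf_ratio = np.clip(rng.normal(cfg.pf_mean, cfg.pf_sd, n), 1.0, 60.0)
    prime = np.where(rng.random(n) < 0.586, "pneumonia", "other")
    surgery = rng.random(n) < 0.136

    icu_days = np.maximum(
        1, np.rint(_lognormal(rng, cfg.icu_los_mean, cfg.icu_los_sd, n))
    ).astype(int)

    # ventilated fraction of the ICU stay; mean chosen so that, with stay
    # and fraction independent, E[vent] = vent_days_mean
    p_frac = np.clip(cfg.vent_days_mean / cfg.icu_los_mean, 0.05, 0.95)
    kappa = 10.0
    frac = rng.beta(p_frac * kappa, (1 - p_frac) * kappa, n)
    vent_days = np.clip(np.rint(frac * icu_days), 1, icu_days).astype(int)

    extra_mean = max(cfg.hosp_los_mean - cfg.icu_los_mean, 0.5)
    extra = np.rint(_lognormal(rng, extra_mean, 2.4 * extra_mean, n)).astype(int)
    hospital_days = icu_days + np.maximum(extra, 0)

    # survival: deaths are a mixture of an early component (uniform on days
    # 1-30) and a late one (uniform on 31-365), so the KM curve drops
    # steeply in the first month and flattens after day 60
    dies = rng.random(n) < cfg.one_year_mortality
    early = rng.random(n) < cfg.early_death_fraction
    early_day = rng.integers(1, 31, n)
    late_day = rng.integers(31, 366, n)
    death_num = np.where(early, early_day, late_day)
    death_day = pd.array(np.where(dies, death_num, 0), dtype="Int64")
    death_day[~dies] = pd.NA
    alive_1yr = ~dies

    readm = np.where(rng.random(n) < 0.18, rng.poisson(6.0, n) + 1, 0)
    readm = np.minimum(readm, hospital_days - icu_days).astype(int)
    stepdown = hospital_days - icu_days - readm
    hdu_days = np.rint(HDU_FRACTION * stepdown).astype(int)

    # discharge to another hospital applies to patients leaving hospital alive
    left_alive = ~dies | (np.where(dies, death_num, 10**6) > hospital_days)
    transfer = (rng.random(n) < 0.08) & left_alive

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "arm": arm,
            "age": age,
            "sex": sex,
            "apache2": apache2.astype(int),
            "pf_ratio": pf_ratio,
            "prime_condition": prime,
            "surgery_admission": surgery,
            "icu_days": icu_days,
            "vent_days": vent_days,
            "hdu_days": hdu_days,
            "hospital_days": hospital_days,
            "death_day": death_day,
            "alive_1yr": alive_1yr,
            "discharged_to_other_hospital": transfer,
            "readmission_days": readm,
        }
    )
    return _cast(df, PATIENT_SCHEMA)


def _generate_crf(patients: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    icu_days = patients["icu_days"].to_numpy()
    n_rows = int(icu_days.sum())
    pid = np.repeat(patients["id"].to_numpy(), icu_days)
    day = np.concatenate([np.arange(1, d + 1) for d in icu_days]) if n_rows else np.array([], int)

    base = np.repeat(rng.normal(3.0, 0.8, len(patients)), icu_days)
    organs = np.clip(np.rint(base - 0.03 * day + rng.normal(0, 0.7, n_rows)), 0, 6)

    vent_len = np.repeat(patients["vent_days"].to_numpy(), icu_days)
    on_vent = day <= vent_len
    rrt_patient = np.repeat(rng.random(len(patients)) < 0.25, icu_days)
    on_rrt = rrt_patient & (rng.random(n_rows) < 0.5)

    df = pd.DataFrame(
        {
            "patient_id": pid,
            "day_index": day,
            "organs_supported": organs.astype(int),
            "on_ventilation": on_vent,
            "on_rrt": on_rrt,
            "xray_count": rng.poisson(0.15, n_rows),
            "chest_drain": rng.random(n_rows) < 0.02,
            "drug_abx": rng.poisson(2.0, n_rows),
            "drug_sedative": rng.poisson(3.0, n_rows),
            "drug_relaxant": rng.poisson(1.0, n_rows),
        }
    )
    return _cast(df, CRF_SCHEMA)


def _zero_inflated(rng, n, p_nonzero, mean_nonzero):
    amounts = _lognormal(rng, mean_nonzero, mean_nonzero, n)
    return np.where(rng.random(n) < p_nonzero, amounts, 0.0)


def _generate_questionnaires(
    cfg: CohortConfig, patients: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    tariff = uk_tto_tariff()
    aids_catalog = np.array(["wheelchair", "walking_frame", "commode", "grab_rail", "other"])

    z_age = (patients["age"].to_numpy() - cfg.age_mean) / cfg.age_sd
    z_ap = (patients["apache2"].to_numpy(float) - cfg.apache_mean) / cfg.apache_sd
    mar = cfg.nonresponse_mar_strength * (z_age + z_ap)

    death = patients["death_day"].fillna(10**6).to_numpy()
    frames = []
    for wave, horizon, base_nr, target_mean in (
        ("6m", DAYS_6M, cfg.nonresponse_6m, cfg.eq5d_mean_6m),
        ("12m", DAYS_12M, cfg.nonresponse_12m, cfg.eq5d_mean_12m),
    ):
        eligible = death > horizon
        ids = patients.loc[eligible, "id"].to_numpy()
        n = len(ids)
        logit_nr = _logit(base_nr) + mar[eligible]
        p_nr = 1.0 / (1.0 + np.exp(-logit_nr))
        returned = rng.random(n) >= p_nr

        n_ret = int(returned.sum())
        df = pd.DataFrame({"patient_id": ids, "wave": wave, "returned": returned})
        for col, dtype in QUESTIONNAIRE_SCHEMA.items():
            if col not in df.columns:
                df[col] = pd.Series(
                    np.nan, index=df.index,
                    dtype=object if dtype == "str" else float,
                )
        if n_ret:
            states = sample_states_with_mean(
                rng, n_ret, target_mean, cfg.eq5d_latent_sd, tariff
            )
            df.loc[returned, "eq5d_state"] = states
            df.loc[returned, "gp_visits"] = rng.poisson(4.0, n_ret)
            df.loc[returned, "outpatient_visits"] = rng.poisson(4.0, n_ret)
            df.loc[returned, "community_visits"] = rng.poisson(3.0, n_ret)
            df.loc[returned, "inpatient_days"] = np.where(
                rng.random(n_ret) < 0.3, rng.poisson(8.0, n_ret) + 1, 0
            )
            n_aids = rng.choice([0, 1, 2], size=n_ret, p=[0.6, 0.3, 0.1])
            df.loc[returned, "aids_items"] = [
                ";".join(sorted(rng.choice(aids_catalog, size=k, replace=False)))
                if k else ""
                for k in n_aids
            ]
            df.loc[returned, "travel_miles"] = np.round(
                _lognormal(rng, 60.0, 60.0, n_ret), 1
            )
            df.loc[returned, "lost_earnings"] = np.round(
                _zero_inflated(rng, n_ret, 0.3, 4700.0), 2
            )
            df.loc[returned, "oop_expenses"] = np.round(
                _zero_inflated(rng, n_ret, 0.15, 300.0), 2
            )
            df.loc[returned, "carer_travel_miles"] = np.round(
                _lognormal(rng, 40.0, 40.0, n_ret), 1
            )
            df.loc[returned, "carer_lost_earnings"] = np.round(
                _zero_inflated(rng, n_ret, 0.2, 1250.0), 2
            )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return _cast(out, QUESTIONNAIRE_SCHEMA)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, daily_crf, questionnaires) for one synthetic trial.

    Deterministic for a fixed ``config.seed``; each table draws from its
    own child stream of the master seed so regenerating one table cannot
    perturb the others.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3)]
    patients = _generate_patients(cfg, streams[0])
    crf = _generate_crf(patients, streams[1])
    quests = _generate_questionnaires(cfg, patients, streams[2])
    for name, df in (("patients", patients), ("daily_crf", crf), ("questionnaires", quests)):
        validate_table(name, df)
    return patients, crf, quests


# ---------------------------------------------------------------------------
# validation and CSV round trip

def _fail(name: str, idx: int, col: str, msg: str) -> None:
    raise ValueError(f"{name} row {idx + 1}, column {col!r}: {msg}")


def validate_table(name: str, df: pd.DataFrame) -> None:
    """Check a cohort table's invariants; errors name the row and column."""
    if name == "patients":
        for col in ("icu_days", "vent_days", "hdu_days", "hospital_days", "readmission_days"):
            bad = df.index[df[col] < 0]
            if len(bad):
                _fail(name, int(bad[0]), col, f"negative value {df.loc[bad[0], col]}")
        bad = df.index[(df["apache2"] < 0) | (df["apache2"] > 71)]
        if len(bad):
            _fail(name, int(bad[0]), "apache2", "APACHE II must lie in [0, 71]")
        bad = df.index[df["vent_days"] > df["icu_days"]]
        if len(bad):
            _fail(name, int(bad[0]), "vent_days", "exceeds icu_days")
        bad = df.index[df["icu_days"] > df["hospital_days"]]
        if len(bad):
            _fail(name, int(bad[0]), "icu_days", "exceeds hospital_days")
        died = df["death_day"].notna() & (df["death_day"] <= 365)
        bad = df.index[died == df["alive_1yr"].astype(bool)]
        if len(bad):
            _fail(name, int(bad[0]), "alive_1yr", "inconsistent with death_day")
    elif name == "daily_crf":
        for col in ("organs_supported", "xray_count", "drug_abx", "drug_sedative", "drug_relaxant"):
            bad = df.index[df[col] < 0]
            if len(bad):
                _fail(name, int(bad[0]), col, f"negative value {df.loc[bad[0], col]}")
        dup = df.duplicated(subset=["patient_id", "day_index"])
        if dup.any():
            _fail(name, int(df.index[dup][0]), "day_index", "duplicate day for patient")
    elif name == "questionnaires":
        money = ["gp_visits", "outpatient_visits", "community_visits", "inpatient_days",
                 "travel_miles", "lost_earnings", "oop_expenses",
                 "carer_travel_miles", "carer_lost_earnings"]
        for col in money:
            bad = df.index[df[col].fillna(0) < 0]
            if len(bad):
                _fail(name, int(bad[0]), col, f"negative value {df.loc[bad[0], col]}")
        not_ret = ~df["returned"].astype(bool)
        for col in ["eq5d_state"] + money:
            bad = df.index[not_ret & df[col].notna()]
            if len(bad):
                _fail(name, int(bad[0]), col, "value present on a non-returned questionnaire")
    else:
        raise KeyError(f"unknown table {name!r}")


def write_cohort(
    tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame], directory: str | Path
) -> dict[str, Path]:
    """Write the three cohort tables as CSV; missing values become empty fields."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (name, (fname, schema)), df in zip(_FILES.items(), tables):
        validate_table(name, df)
        path = directory / fname
        df.to_csv(path, index=False, na_rep="")
        paths[name] = path
    return paths


def read_cohort(
    directory: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read cohort CSVs back, restoring dtypes and re-checking invariants.

    Malformed rows are reported with their (1-based) row number and column.
    """
    directory = Path(directory)
    out = []
    for name, (fname, schema) in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
        str_cols = {c: str for c, dt in schema.items() if dt == "str"}
        raw = pd.read_csv(path, dtype=str_cols)
        if raw.empty:
            df = _cast(pd.DataFrame({c: [] for c in schema}), schema)
        else:
            try:
                df = _cast(raw, schema)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{fname}: {exc}") from exc
        # empty aids_items strings survive the round trip as NA; normalise
        if name == "questionnaires":
            ret = df["returned"].astype(bool) & df["eq5d_state"].notna()
            df.loc[ret & df["aids_items"].isna(), "aids_items"] = ""
        validate_table(name, df)
        out.append(df)
    return tuple(out)
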