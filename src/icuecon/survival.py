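"""One-year quality-adjusted survival by partitioned Kaplan-Meier areas.

The cohort's year is split into a ventilation period and four follow-up
periods ending at 3, 6, 9 and 12 months (91.3 / 182.6 / 274.0 / 365 days).
Each period contributes the restricted mean survival time in the period
(the area under the Kaplan-Meier curve, in years) multiplied by the
period's utility. The ventilation period instead contributes the cohort's
mean number of ventilated days weighted by the utility of an unconscious
patient (-0.4). Utilities are observed at 6 and 12 months; assuming a
linear change in quality of life between assessments, the 3- and 9-month
utilities lie on the line through the two observed points:

    u9 = (u6 + u12) / 2        u3 = u6 - (u12 - u6) / 2

so that  QALY = u_unc * vent_days/365.25 + u3*A(t_v, 91.3)
              + u6*A(91.3, 182.6) + u9*A(182.6, 274) + u12*A(274, 365)

with A(a, b) the KM area over [a, b] in years and t_v the mean ventilated
days. The 95 % CI comes from a nonparametric bootstrap over patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.api import Logit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DAYS_PER_YEAR = 365.25
HORIZON = 365.0
PERIOD_ENDS = (91.3, 182.6, 274.0, 365.0)  # 3, 6, 9, 12 months in days


class SeparationError(RuntimeError):
    """Raised when a logistic model is not identified (perfect separation)."""


@dataclass
class KMCurve:
    """Product-limit survival estimate: step function S(t) on [0, horizon]."""

    event_times: np.ndarray   # distinct times with at least one event
    survival_probs: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    horizon: float = HORIZON


@dataclass
class QALYResult:
    vent_period_years: float
    period_bounds: tuple[float, ...]
    period_utilities: tuple[float, ...]  # (u_vent, u3, u6, u9, u12)
    period_areas: tuple[float, ...]      # years, aligned with bounds
    qaly: float
    ci: tuple[float, float] | None


def km_estimate(times, event_flags, horizon: float = HORIZON) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``times`` are days since randomisation; ``event_flags`` is True for a
    death, False for censoring. At tied times events precede censorings.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one observation")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    t = np.sort(times)
    te = np.sort(times[events])
    uniq, d = np.unique(te, return_counts=True)
    # events before censorings at ties: at risk = all with time >= u
    at_risk = t.size - np.searchsorted(t, uniq, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        event_times=uniq.astype(float),
        survival_probs=surv,
        n_at_risk=at_risk.astype(int),
        horizon=horizon,
    )


def km_survival_at(curve: KMCurve, t: float) -> float:
    """S(t): right-continuous step function."""
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return float(curve.survival_probs[idx]) if idx >= 0 else 1.0


def restricted_mean(curve: KMCurve, a: float, b: float) -> float:
    """Area under S(t) over [a, b] in years (exact step integration)."""
    if not (0 <= a < b <= curve.horizon):
        raise ValueError(f"bounds must satisfy 0 <= a < b <= horizon, got [{a}, {b}]")
    # break points inside (a, b)
    cuts = curve.event_times[(curve.event_times > a) & (curve.event_times < b)]
    grid = np.concatenate(([a], cuts, [b]))
    if curve.event_times.size == 0:  # no events: S == 1 throughout
        s = np.ones(grid.size - 1)
    else:
        idx = np.searchsorted(curve.event_times, grid[:-1], side="right") - 1
        s = np.where(idx >= 0, curve.survival_probs[np.maximum(idx, 0)], 1.0)
    area_days = float(np.dot(s, np.diff(grid)))
    return area_days / DAYS_PER_YEAR


def interpolate_utilities(u6: float, u12: float) -> tuple[float, float]:
    """3- and 9-month utilities on the straight line through the 6- and
    12-month assessments (the 3-month value extrapolates that line back)."""
    lo = -0.594 - 1e-9
    for name, u in (("u6", u6), ("u12", u12)):
        if not lo <= u <= 1.0:
            raise ValueError(f"{name} must lie in [-0.594, 1], got {u}")
    u9 = (u6 + u12) / 2.0
    u3 = u6 - (u12 - u6) / 2.0
    return u3, u9


def _point_qaly(times, events, mean_vent_days, u3, u6, u9, u12, unconscious_utility):
    curve = km_estimate(times, events)
    bounds = (mean_vent_days,) + PERIOD_ENDS
    areas = []
    us = (u3, u6, u9, u12)
    lo = mean_vent_days
    for hi in PERIOD_ENDS:
        areas.append(restricted_mean(curve, lo, hi) if lo < hi else 0.0)
        lo = hi
    vent_years = mean_vent_days / DAYS_PER_YEAR
    qaly = unconscious_utility * vent_years + float(np.dot(areas, us))
    return curve, bounds, tuple(areas), vent_years, qaly


def quality_adjusted_survival(
    times,
    event_flags,
    mean_vent_days: float,
    u6: float,
    u12: float,
    unconscious_utility: float = -0.4,
    n_boot: int = 1000,
    seed: int | None = None,
) -> QALYResult:
    """Cohort quality-adjusted survival at one year (see module docstring).

    ``mean_vent_days`` may be a scalar (cohort mean) or a per-patient
    array, in which case the bootstrap resamples ventilated days jointly
    with survival. Set ``n_boot=0`` to skip the CI.
    """
    times = np.asarray(times, float)
    events = np.asarray(event_flags, bool)
    vent = np.asarray(mean_vent_days, float)
    per_patient = vent.ndim == 1
    if per_patient and vent.size != times.size:
        raise ValueError("per-patient vent days must match the number of patients")
    mv = float(vent.mean()) if per_patient else float(vent)
    if mv < 0:
        raise ValueError("mean ventilated days must be non-negative")
    if mv >= PERIOD_ENDS[0]:
        raise ValueError(
            f"mean ventilated days {mv} reaches into the second period "
            f"(>= {PERIOD_ENDS[0]} d); the ventilation period must end in the first"
        )
    u3, u9 = interpolate_utilities(u6, u12)
    _, bounds, areas, vent_years, qaly = _point_qaly(
        times, events, mv, u3, u6, u9, u12, unconscious_utility
    )
    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        n = times.size
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            mv_b = float(vent[idx].mean()) if per_patient else mv
            reps[b] = _point_qaly(
                times[idx], events[idx], mv_b, u3, u6, u9, u12, unconscious_utility
            )[4]
        ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return QALYResult(
        vent_period_years=vent_years,
        period_bounds=bounds,
        period_utilities=(unconscious_utility, u3, u6, u9, u12),
        period_areas=areas,
        qaly=float(qaly),
        ci=ci,
    )


def adjusted_mortality_or(
    patients: pd.DataFrame, grouping: str
) -> tuple[float, tuple[float, float]]:
    """Odds ratio of one-year death for a patient subgroup, adjusted for sex
    and PaO2:FiO2 ratio by maximum-likelihood logistic regression (Wald CI).

    ``grouping``: 'age' (>= 65 vs younger), 'apache' (> 26 vs lower) or
    'arm' (hfov vs conventional).
    """
    if grouping == "age":
        indicator = (patients["age"] >= 65).astype(float)
    elif grouping == "apache":
        indicator = (patients["apache2"] > 26).astype(float)
    elif grouping == "arm":
        indicator = (patients["arm"] == "hfov").astype(float)
    else:
        raise KeyError(f"unknown grouping {grouping!r}; use 'age', 'apache' or 'arm'")
    died = 1.0 - patients["alive_1yr"].astype(bool).astype(float)
    for label, g in (("group", indicator), ("comparator", 1 - indicator)):
        outcomes = died[g == 1].unique() if (g == 1).any() else []
        if len(outcomes) < 2:
            raise SeparationError(
                f"{label} does not contain both outcomes; the logistic model "
                "is separated and the odds ratio is not identified"
            )
    X = pd.DataFrame(
        {
            "const": 1.0,
            "group": indicator.to_numpy(),
            "female": (patients["sex"] == "female").astype(float).to_numpy(),
            "pf_ratio": patients["pf_ratio"].to_numpy(float),
        }
    )
    try:
        fit = Logit(died.to_numpy(), X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    beta = fit.params["group"]
    if abs(beta) > 15:
        raise SeparationError("quasi-separation: group coefficient diverged")
    lo, hi = fit.conf_int().loc["group"]
    return float(np.exp(beta)), (float(np.exp(lo)), float(np.exp(hi)))
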