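"""Partitioned Kaplan-Meier QALY estimation and adjusted mortality ORs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter

from icuecon.cohort import CohortConfig, generate_cohort
from icuecon.survival import (
    DAYS_PER_YEAR,
    SeparationError,
    adjusted_mortality_or,
    interpolate_utilities,
    km_estimate,
    km_survival_at,
    quality_adjusted_survival,
    restricted_mean,
)


def oracle_product_limit(times, events, t):
    """Brute-force product-limit S(t): iterate unique event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    s = 1.0
    for u in sorted(set(times[events])):
        if u > t:
            break
        at_risk = np.sum(times >= u)
        deaths = np.sum((times == u) & events)
        s *= 1.0 - deaths / at_risk
    return s


def test_km_hand_cases():
    c = km_estimate([365, 365, 365], [False, False, False])
    assert km_survival_at(c, 364) == 1.0

    c = km_estimate([1, 2, 3], [True, False, True])
    assert km_survival_at(c, 1) == pytest.approx(2 / 3)
    assert km_survival_at(c, 3) == pytest.approx(0.0)

    c = km_estimate([10], [True])
    assert km_survival_at(c, 9.9) == 1.0
    assert km_survival_at(c, 10) == 0.0


def test_km_empty_input_rejected():
    with pytest.raises(ValueError):
        km_estimate([], [])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(1, 30), st.booleans()), min_size=1, max_size=20
    )
)
def test_km_matches_bruteforce_oracle_small_cohorts(data):
    times = [t for t, _ in data]
    events = [e for _, e in data]
    curve = km_estimate(times, events)
    for t in range(0, 32):
        assert km_survival_at(curve, t) == pytest.approx(
            oracle_product_limit(times, events, t), abs=1e-12
        )


def test_km_agrees_with_lifelines(small_cohort):
    patients = small_cohort[0]
    death = patients["death_day"].fillna(10**6)
    died = (death <= 365).to_numpy()
    times = np.where(died, death.to_numpy(float), 365.0)
    curve = km_estimate(times, died)
    kmf = KaplanMeierFitter().fit(times, died)
    for t in (1.0, 15.0, 30.0, 100.0, 364.0):
        assert km_survival_at(curve, t) == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
        )


def test_restricted_mean_cases():
    c = km_estimate([400.0], [False])  # S == 1 throughout
    assert restricted_mean(c, 0, 365) == pytest.approx(365 / 365.25)

    c = km_estimate([0.0, 400.0], [True, False])  # S == 0.5 from t=0
    assert restricted_mean(c, 0, 100) == pytest.approx(50 / 365.25)

    with pytest.raises(ValueError):
        restricted_mean(c, 100, 50)
    with pytest.raises(ValueError):
        restricted_mean(c, 0, 400)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    data=st.lists(st.tuples(st.integers(1, 364), st.booleans()), min_size=1, max_size=15),
    cut=st.floats(1.0, 364.0),
)
def test_restricted_mean_additive_over_partition(data, cut):
    curve = km_estimate([t for t, _ in data], [e for _, e in data])
    whole = restricted_mean(curve, 0, 365)
    parts = restricted_mean(curve, 0, cut) + restricted_mean(curve, cut, 365)
    assert whole == pytest.approx(parts, abs=1e-12)


def test_interpolate_utilities():
    assert interpolate_utilities(0.6, 0.6) == (0.6, 0.6)
    u3, u9 = interpolate_utilities(0.5622, 0.5831)
    assert u9 == pytest.approx(0.57265)
    assert u3 == pytest.approx(0.5622 - (0.5831 - 0.5622) / 2)
    assert interpolate_utilities(0.4, 0.6)[0] == pytest.approx(0.3)
    with pytest.raises(ValueError, match="u6"):
        interpolate_utilities(-0.7, 0.5)


def test_qaly_full_health_and_all_dead():
    n = 50
    res = quality_adjusted_survival(
        np.full(n, 365.0), np.zeros(n, bool), 0.0, 1.0, 1.0, n_boot=0
    )
    assert res.qaly == pytest.approx(365 / 365.25)

    res = quality_adjusted_survival(
        np.zeros(n), np.ones(n, bool), 0.0, 0.5, 0.5, n_boot=0
    )
    assert res.qaly == pytest.approx(0.0)


def test_qaly_equals_restricted_mean_when_utilities_one():
    rng = np.random.default_rng(3)
    times = rng.integers(1, 366, 100).astype(float)
    events = rng.random(100) < 0.5
    times = np.where(events, times, 365.0)
    res = quality_adjusted_survival(times, events, 0.0, 1.0, 1.0, n_boot=0)
    curve = km_estimate(times, events)
    assert res.qaly == pytest.approx(restricted_mean(curve, 0, 365), abs=1e-12)


def test_qaly_decomposition_and_bounds():
    rng = np.random.default_rng(7)
    times = np.where(rng.random(200) < 0.5, rng.integers(1, 366, 200), 365).astype(float)
    events = times < 365
    res = quality_adjusted_survival(times, events, 11.0, 0.5622, 0.5831, n_boot=0)
    recon = res.period_utilities[0] * res.vent_period_years + float(
        np.dot(res.period_areas, res.period_utilities[1:])
    )
    assert res.qaly == pytest.approx(recon, abs=1e-12)
    rm = restricted_mean(km_estimate(times, events), 0, 365)
    assert -0.4 * res.vent_period_years <= res.qaly <= rm


def test_qaly_rejects_vent_beyond_first_period():
    with pytest.raises(ValueError, match="period"):
        quality_adjusted_survival([365.0], [False], 100.0, 0.5, 0.5, n_boot=0)


def _true_mixture_qaly(p=0.512, f=0.9, vent=11.0, u6=0.5622, u12=0.5831):
    """Exact cohort QALY when death days are the uniform integer mixture."""
    u3, u9 = interpolate_utilities(u6, u12)

    def surv(t):  # P(T > t) for integer-day deaths
        k = np.floor(t)
        return 1 - p * f * np.minimum(k, 30) / 30 - p * (1 - f) * np.clip(k - 30, 0, 335) / 335

    def area(a, b):
        # S is constant on [k, k+1); integrate exactly over unit pieces
        grid = np.concatenate([[a], np.arange(np.ceil(a), np.floor(b) + 1), [b]])
        grid = np.unique(grid)
        return float(np.dot(surv(grid[:-1]), np.diff(grid))) / DAYS_PER_YEAR

    return (-0.4 * vent / DAYS_PER_YEAR + u3 * area(vent, 91.3)
            + u6 * area(91.3, 182.6) + u9 * area(182.6, 274.0) + u12 * area(274.0, 365.0))


def test_bootstrap_ci_nominal_coverage():
    """Percentile bootstrap CI covers the true cohort QALY ~95 % of the
    time over repeated cohorts drawn from the survival mixture."""
    truth = _true_mixture_qaly()
    rng = np.random.default_rng(2024)
    n, reps, covered = 200, 500, 0
    for r in range(reps):
        dies = rng.random(n) < 0.512
        early = rng.random(n) < 0.9
        day = np.where(early, rng.integers(1, 31, n), rng.integers(31, 366, n))
        times = np.where(dies, day, 365).astype(float)
        res = quality_adjusted_survival(
            times, dies, 11.0, 0.5622, 0.5831, n_boot=250, seed=r
        )
        covered += res.ci[0] <= truth <= res.ci[1]
    assert 0.92 <= covered / reps <= 0.98


def test_adjusted_or_null_near_one():
    ors = []
    for seed in (1, 2, 3, 4):
        patients, _, _ = generate_cohort(CohortConfig(n_patients=3000, seed=seed))
        o, _ = adjusted_mortality_or(patients, "arm")  # arm has no mortality effect
        ors.append(o)
    assert abs(np.log(np.mean(ors))) < 0.15


def test_adjusted_or_recovers_known_log_odds():
    """Balanced two-group design with true log-odds 1.0 and no covariate
    effects: the Wald CI should cover e at ~95 % across replicates."""
    rng = np.random.default_rng(5)
    n, reps, covered = 400, 200, 0
    for _ in range(reps):
        group = np.repeat([0, 1], n // 2)
        p = 1 / (1 + np.exp(-(-0.5 + 1.0 * group)))
        died = rng.random(n) < p
        patients = pd.DataFrame(
            {
                "age": np.where(group == 1, 70.0, 50.0),
                "apache2": 20,
                "arm": "conventional",
                "sex": rng.choice(["male", "female"], n),
                "pf_ratio": rng.normal(15, 5, n),
                "alive_1yr": ~died,
            }
        )
        o, (lo, hi) = adjusted_mortality_or(patients, "age")
        covered += lo <= np.e <= hi
    assert 0.90 <= covered / reps <= 0.99


def test_separation_reported():
    patients = pd.DataFrame(
        {
            "age": [70.0] * 5 + [50.0] * 5,
            "apache2": 20,
            "arm": "conventional",
            "sex": "male",
            "pf_ratio": 15.0,
            "alive_1yr": [False] * 5 + [True] * 5,  # group determines outcome
        }
    )
    with pytest.raises(SeparationError):
        adjusted_mortality_or(patients, "age")
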