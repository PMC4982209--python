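"""EQ-5D-3L utility scoring with the UK time-trade-off value set.

An EQ-5D-3L health state is a five-character string such as ``"21123"``,
one digit per dimension (mobility, self-care, usual activities,
pain/discomfort, anxiety/depression), each at level 1 (no problems),
2 (some problems) or 3 (extreme problems). A country-specific tariff maps
each of the 243 admissible states to a societal utility on a scale where
1 is full health and 0 is dead; the UK TTO tariff reaches down to -0.594
for state ``"33333"``.

The tariff is additive-decrement: starting from 1.0 one subtracts a
constant for any departure from full health, a per-dimension decrement at
level 2 or 3, and an extra decrement if any dimension is at level 3.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


@dataclass(frozen=True)
class TariffCoefficients:
    """Additive decrements of a 3-level EQ-5D value set."""

    constant_decrement: float
    level2_decrements: Mapping[str, float]
    level3_decrements: Mapping[str, float]
    n3_decrement: float
    unconscious_utility: float = -0.4

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            if dim not in self.level2_decrements or dim not in self.level3_decrements:
                raise ValueError(f"tariff is missing decrements for dimension {dim!r}")
        decs = [self.constant_decrement, self.n3_decrement]
        decs += [self.level2_decrements[d] for d in DIMENSIONS]
        decs += [self.level3_decrements[d] for d in DIMENSIONS]
        if any(d < 0 for d in decs):
            raise ValueError("all tariff decrements must be non-negative")
        for dim in DIMENSIONS:
            if self.level3_decrements[dim] < self.level2_decrements[dim]:
                raise ValueError(f"level-3 decrement below level-2 for {dim!r}")

    @property
    def minimum_utility(self) -> float:
        """Utility of the worst state, 1 - constant - sum(level3) - N3."""
        return 1.0 - self.constant_decrement - sum(
            self.level3_decrements[d] for d in DIMENSIONS
        ) - self.n3_decrement


def uk_tto_tariff() -> TariffCoefficients:
    """Load the bundled UK TTO value set."""
    ref = importlib.resources.files("icuecon.data").joinpath("uk_tto_tariff.yaml")
    raw = yaml.safe_load(ref.read_text())
    return TariffCoefficients(
        constant_decrement=float(raw["constant_decrement"]),
        level2_decrements={k: float(v) for k, v in raw["level2_decrements"].items()},
        level3_decrements={k: float(v) for k, v in raw["level3_decrements"].items()},
        n3_decrement=float(raw["n3_decrement"]),
        unconscious_utility=float(raw["unconscious_utility"]),
    )


def _parse_state(state: str) -> tuple[int, ...]:
    if not isinstance(state, str) or len(state) != 5:
        raise ValueError(f"EQ-5D state must be a 5-character string, got {state!r}")
    levels = []
    for pos, ch in enumerate(state, start=1):
        if ch not in "123":
            raise ValueError(
                f"invalid level {ch!r} at position {pos} of state {state!r}; "
                "each digit must be 1, 2 or 3"
            )
        levels.append(int(ch))
    return tuple(levels)


def eq5d_utility(state: str, coeffs: TariffCoefficients | None = None) -> float:
    """Utility of one EQ-5D-3L state under an additive tariff."""
    if coeffs is None:
        coeffs = uk_tto_tariff()
    levels = _parse_state(state)
    u = 1.0
    if any(lv > 1 for lv in levels):
        u -= coeffs.constant_decrement
    for dim, lv in zip(DIMENSIONS, levels):
        if lv == 2:
            u -= coeffs.level2_decrements[dim]
        elif lv == 3:
            u -= coeffs.level3_decrements[dim]
    if any(lv == 3 for lv in levels):
        u -= coeffs.n3_decrement
    return u


def all_states() -> list[str]:
    """All 243 admissible EQ-5D-3L states, lexicographic order."""
    return ["".join(p) for p in product("123", repeat=5)]


def state_utilities(coeffs: TariffCoefficients | None = None) -> pd.Series:
    """Utilities of all 243 states, indexed by state string."""
    if coeffs is None:
        coeffs = uk_tto_tariff()
    states = all_states()
    return pd.Series([eq5d_utility(s, coeffs) for s in states], index=states)


def mean_wave_utility(
    questionnaires: pd.DataFrame,
    wave: str,
    coeffs: TariffCoefficients | None = None,
) -> tuple[float, tuple[float, float], int]:
    """Mean survivor utility at one follow-up wave with a normal 95 % CI.

    Uses all returned questionnaires at the wave, ignoring non-returns;
    this mirrors pooling "all available questionnaires" rather than the
    both-wave complete cases used for costs.
    """
    if coeffs is None:
        coeffs = uk_tto_tariff()
    sel = questionnaires[
        (questionnaires["wave"] == wave) & questionnaires["returned"].astype(bool)
    ]
    n = len(sel)
    if n < 2:
        raise ValueError(
            f"need at least 2 returned questionnaires at wave {wave!r}, got {n}"
        )
    utils = np.array([eq5d_utility(s, coeffs) for s in sel["eq5d_state"]])
    mean = float(utils.mean())
    se = float(utils.std(ddof=1) / np.sqrt(n))
    return mean, (mean - 1.96 * se, mean + 1.96 * se), n


def load_reference_values() -> dict:
    """Bundled age-/sex-matched population EQ-5D reference summaries."""
    ref = importlib.resources.files("icuecon.data").joinpath("reference_eq5d.yaml")
    return yaml.safe_load(ref.read_text())


def compare_to_reference(
    band_stats: Mapping[str, Mapping[str, float]],
    reference: Mapping | None = None,
) -> pd.DataFrame:
    """Welch two-sample t test of survivor utility against reference values.

    ``band_stats`` maps band name -> {"mean": .., "sd": .., "n": ..}.
    The reference supplies mean and sd per band plus the assumed reference
    sample size ``n_ref``. Returns one row per band with the difference,
    t statistic and two-sided p value.
    """
    if reference is None:
        reference = load_reference_values()
    n_ref = int(reference["n_ref"])
    rows = []
    for band, s in band_stats.items():
        if band not in reference["bands"]:
            raise KeyError(f"band {band!r} missing from the reference table")
        n1 = int(s["n"])
        if n1 < 2 or n_ref < 2:
            raise ValueError(f"band {band!r}: Welch t needs n >= 2 in both samples")
        m1, sd1 = float(s["mean"]), float(s["sd"])
        ref = reference["bands"][band]
        m2, sd2 = float(ref["mean"]), float(ref["sd"])
        v1, v2 = sd1**2 / n1, sd2**2 / n_ref
        t = (m1 - m2) / np.sqrt(v1 + v2) if (v1 + v2) > 0 else 0.0
        if v1 + v2 > 0:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n_ref - 1))
            p = 2 * stats.t.sf(abs(t), df)
        else:
            df, p = np.inf, 1.0
        rows.append(
            {"band": band, "difference": m1 - m2, "t": float(t), "df": float(df), "p": float(p)}
        )
    return pd.DataFrame(rows).set_index("band")


# ---------------------------------------------------------------------------
# Calibrated state sampling (used by the synthetic cohort generator)

def _value_grid(coeffs: TariffCoefficients) -> tuple[np.ndarray, list[str]]:
    utils = state_utilities(coeffs)
    # one representative state per distinct utility value; ties resolved to
    # the lexicographically smallest state so sampling is deterministic
    by_value: dict[float, str] = {}
    for state, u in utils.items():
        key = round(float(u), 9)
        if key not in by_value or state < by_value[key]:
            by_value[key] = state
    values = np.array(sorted(by_value))
    states = [by_value[v] for v in values]
    return values, states


def _expected_mapped_mean(mu: float, sigma: float, values: np.ndarray) -> float:
    # nearest-value quantisation of N(mu, sigma) onto the tariff grid
    mids = (values[:-1] + values[1:]) / 2
    upper = np.append(mids, np.inf)
    lower = np.insert(mids, 0, -np.inf)
    probs = stats.norm.cdf(upper, mu, sigma) - stats.norm.cdf(lower, mu, sigma)
    return float(np.dot(probs, values))


def sample_states_with_mean(
    rng: np.random.Generator,
    n: int,
    target_mean: float,
    latent_sd: float,
    coeffs: TariffCoefficients | None = None,
) -> list[str]:
    """Draw EQ-5D states whose tariff values average to ``target_mean``.

    A latent utility is drawn from a normal and mapped to the admissible
    state with the nearest tariff value. Because the tariff grid is bounded
    and uneven, the latent mean is first calibrated (Brent root find) so
    the mean of the *mapped* values equals the target; without this the
    ceiling at 1.0 would bias the sample mean down by roughly 0.02.
    """
    if coeffs is None:
        coeffs = uk_tto_tariff()
    values, states = _value_grid(coeffs)
    if not values[0] <= target_mean <= values[-1]:
        raise ValueError(f"target mean {target_mean} outside the tariff range")

    def gap(mu: float) -> float:
        return _expected_mapped_mean(mu, latent_sd, values) - target_mean

    mu = optimize.brentq(gap, target_mean - 4 * latent_sd, target_mean + 4 * latent_sd)
    latent = rng.normal(mu, latent_sd, size=n)
    idx = np.abs(latent[:, None] - values[None, :]).argmin(axis=1)
    return [states[i] for i in idx]
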