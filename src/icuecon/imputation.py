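"""Multiple imputation of missing post-hospital costs, pooled by Rubin's rules.

Among one-year survivors the post-hospital cost components are missing
whenever the 6- or 12-month questionnaire was not returned. Because
non-response depends on observed covariates (age, illness severity), a
complete-case mean is biased; chained-equation multiple imputation with
those covariates as predictors removes the bias under the
missing-at-random assumption.

The conditional model is a truncated Bayesian normal regression: for each
incomplete cost variable, regression parameters are drawn from their
posterior given the observed cases, and missing values are drawn from the
resulting predictive normal truncated below at the floor (zero by
default), so imputed costs can never be negative. Variables are cycled in
chained-equation fashion, each imputed dataset comes from its own
independent chain, and any per-dataset estimate is pooled with Rubin's
rules:

    point = mean of the m estimates
    total variance = W-bar + (1 + 1/m) * B
    df = (m - 1) * (1 + W-bar / ((1 + 1/m) * B))**2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PREDICTORS = ("age", "sex", "apache2", "pf_ratio", "arm", "icu_days")


@dataclass
class ImputationSpec:
    m: int = 10
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    truncation_floor: float = 0.0
    iterations: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.truncation_floor < 0:
            raise ValueError("truncation_floor must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class PooledEstimate:
    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]


def impute_costs(
    data: pd.DataFrame,
    impute_columns: list[str] | tuple[str, ...],
    spec: ImputationSpec | None = None,
) -> list[pd.DataFrame]:
    """Chained-equation imputation of the named cost columns.

    ``data`` holds one row per patient: the (possibly incomplete) cost
    columns plus the predictor covariates, which must be complete.
    Returns ``spec.m`` completed copies of ``data``: observed entries are
    untouched and identical across copies; only imputed cells vary.
    Deterministic for a fixed ``spec.seed``.
    """
    spec = spec or ImputationSpec()
    spec.validate()
    missing_preds = [p for p in spec.predictors if p not in data.columns]
    if missing_preds:
        raise KeyError(f"predictor columns absent from data: {missing_preds}")
    for p in spec.predictors:
        if data[p].isna().any():
            raise ValueError(f"predictor column {p!r} must be complete")
    for col in impute_columns:
        n_obs = int(data[col].notna().sum())
        if n_obs == 0:
            raise ValueError(f"no complete cases for {col!r}; cannot impute")

    work = pd.DataFrame(index=pd.RangeIndex(len(data)))
    for col in impute_columns:
        work[col] = pd.to_numeric(data[col].to_numpy(), errors="raise")
    for p in spec.predictors:
        s = data[p]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == "boolean":
            codes = pd.Categorical(s).codes.astype(float)
            work[p] = codes
        else:
            work[p] = s.to_numpy(dtype=float)

    any_missing = work[list(impute_columns)].isna().any().any()
    if not any_missing:
        return [data.copy() for _ in range(spec.m)]

    # one independent chain per imputed dataset, so between-imputation
    # variance is not deflated by autocorrelation along a single chain
    completed = []
    for child in np.random.SeedSequence(spec.seed).spawn(spec.m):
        rng = np.random.default_rng(child)
        filled = _run_chain(work, list(impute_columns), list(spec.predictors),
                            spec, rng)
        out = data.copy()
        for col in impute_columns:
            observed = data[col].notna().to_numpy()
            vals = filled[col].to_numpy(float)
            # keep observed entries bit-identical to the input
            vals[observed] = data[col].to_numpy(float)[observed]
            out[col] = vals
        completed.append(out)
    return completed


def _draw_truncated_regression(rng, y_obs, X_obs, X_mis, floor):
    """Posterior draw of a normal linear model on the observed cases, then
    predictive draws for the missing rows truncated below at ``floor``."""
    n, p = X_obs.shape
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    beta_hat = xtx_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    sigma2 = max(sigma2, 1e-12)
    cov = sigma2 * xtx_inv
    cov = (cov + cov.T) / 2 + 1e-12 * np.eye(p)
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    mu = X_mis @ beta
    sigma = np.sqrt(sigma2)
    a = (floor - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng)


def _run_chain(work, impute_columns, predictors, spec, rng):
    cur = work.copy()
    missing = {c: work[c].isna().to_numpy() for c in impute_columns}
    # initial fill: resample observed values
    for c in impute_columns:
        obs_vals = work.loc[~missing[c].astype(bool), c].to_numpy(float)
        cur.loc[missing[c], c] = rng.choice(obs_vals, size=int(missing[c].sum()))
    for _ in range(spec.iterations):
        for c in impute_columns:
            others = [o for o in impute_columns if o != c]
            X = np.column_stack(
                [np.ones(len(cur))]
                + [cur[p].to_numpy(float) for p in predictors]
                + [cur[o].to_numpy(float) for o in others]
            )
            m = missing[c]
            cur.loc[m, c] = _draw_truncated_regression(
                rng, work.loc[~m, c].to_numpy(float), X[~m], X[m],
                spec.truncation_floor,
            )
    return cur


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool m point estimates and their within-imputation variances."""
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be 1-d of equal length")
    m = est.size
    if m < 2:
        raise ValueError(f"need at least 2 imputations to pool, got {m}")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    point = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        half = stats.t.ppf(0.975, df) * np.sqrt(total)
    else:
        df = np.inf
        half = stats.norm.ppf(0.975) * np.sqrt(total)
    return PooledEstimate(
        point=point,
        within_var=within,
        between_var=between,
        total_var=float(total),
        df=float(df),
        ci=(point - float(half), point + float(half)),
    )


def pooled_column_mean(datasets: list[pd.DataFrame], column: str) -> PooledEstimate:
    """Rubin-pooled mean of one column across m completed datasets."""
    ests, vars = [], []
    for df in datasets:
        x = df[column].to_numpy(float)
        if np.isnan(x).any():
            raise ValueError(f"dataset still contains missing values in {column!r}")
        ests.append(x.mean())
        vars.append(x.var(ddof=1) / len(x))
    return rubin_pool(ests, vars)
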