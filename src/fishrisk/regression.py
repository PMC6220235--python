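"""Regression of national slavery prevalence on fisheries metrics.

Multiple linear regression of country-level prevalence (victims per 1000
population) on candidate fisheries performance measures, with exhaustive
subset enumeration ranked by the small-sample-corrected Akaike information
criterion (AICc), a configurable outlier-exclusion list, and a Monte Carlo
sensitivity analysis that propagates across-year variability of the
fisheries metrics and the reported 95% CIs of the prevalence estimates into
a distribution of R² values.

AICc uses the Gaussian-likelihood form with the error variance counted as a
fitted parameter:

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1),   k = p + 1,

where p is the number of regression coefficients including the intercept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InputError, UndefinedResultError

logger = logging.getLogger(__name__)

#: Countries excluded from the regression by default. The analysis treats
#: India as an outlier: its national prevalence is dominated by land-based
#: slavery in landlocked states and misrepresents its fisheries.
DEFAULT_EXCLUSIONS = ("IND", "India")

_ZERO_TSS = 1e-300


@dataclass(frozen=True)
class RegressionFit:
    """One fitted linear model of prevalence on a predictor subset."""

    predictors: tuple[str, ...]
    coefficients: dict  # includes "intercept"
    r2: float
    f_pvalue: float
    aicc: float
    n: int
    rss: float
    zero_tss: bool = False  # response was constant; R² reported as 0


@dataclass(frozen=True)
class MonteCarloResult:
    """R² distribution from one Monte Carlo sensitivity scenario."""

    scenario: str  # "all" | "fisheries_only" | "slavery_only"
    r2: np.ndarray = field(repr=False)
    median_r2: float = 0.0
    seed: int = 0
    n_runs: int = 0
    n_skipped: int = 0


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample-corrected AIC for a Gaussian linear model.

    Parameters: ``rss`` residual sum of squares, ``n`` observations, ``p``
    fitted regression coefficients including the intercept. The error
    variance is counted as an additional parameter (k = p + 1), so the
    correction denominator is n - k - 1 and requires n > p + 2.
    """
    k = p + 1
    if n <= k + 1:
        raise UndefinedResultError(
            f"AICc undefined: need n > {k + 1} observations for {p} coefficients, got n={n}"
        )
    if rss < 0:
        raise InputError("RSS must be nonnegative")
    if rss == 0.0:
        return -math.inf  # perfect fit dominates any ranking
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal does not reduce the design-matrix rank."""
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    full_rank = np.linalg.matrix_rank(design)
    out = []
    for j, col in enumerate(X.columns):
        reduced = np.delete(design, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(col)
    return out


def fit_ols(response: pd.Series, predictors: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares of prevalence on the given metric columns.

    Requires n >= p + 2 complete observations and a full-rank design. A
    constant response yields R² = 0 with ``zero_tss`` set rather than NaN.
    """
    y = response.astype(float)
    X = predictors.astype(float)
    if y.isna().any() or X.isna().any().any():
        raise InputError("missing values in response or predictors")
    n, p_vars = len(X), X.shape[1]
    if n < p_vars + 3:
        raise InputError(f"too few observations: n={n} for {p_vars} predictors")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < p_vars + 1:
        bad = _collinear_columns(X)
        raise InputError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    tss = float(res.centered_tss)
    zero_tss = tss <= _ZERO_TSS
    r2 = 0.0 if zero_tss else float(res.rsquared)
    coefs = {"intercept": float(res.params.iloc[0])}
    coefs.update({c: float(res.params[c]) for c in X.columns})
    return RegressionFit(
        predictors=tuple(X.columns),
        coefficients=coefs,
        r2=r2,
        f_pvalue=float("nan") if zero_tss else float(res.f_pvalue),
        aicc=aicc(rss, n, p_vars + 1),
        n=n,
        rss=rss,
        zero_tss=zero_tss,
    )


def _align(
    metrics: pd.DataFrame, slavery: pd.DataFrame, exclusions
) -> tuple[pd.DataFrame, pd.Series]:
    common = metrics.index.intersection(slavery.index)
    keep = [c for c in common if c not in set(exclusions)]
    return metrics.loc[keep], slavery.loc[keep, "prevalence_per_1000"]


def select_model(
    metrics: pd.DataFrame,
    slavery: pd.DataFrame,
    candidates: tuple[str, ...] = ("pct_unreported", "landed_value_per_kg", "tonnes_per_fisher"),
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS,
) -> tuple[RegressionFit, pd.DataFrame]:
    """Exhaustive best-subset selection ranked by AICc.

    Enumerates every non-empty subset of ``candidates``, fits each by OLS on
    the countries common to both tables (minus the exclusion list), and
    ranks by AICc. Returns the best fit and the full ranking table
    (columns: predictors, n_predictors, aicc, delta_aicc, r2, f_pvalue).
    """
    if not candidates:
        raise InputError("need at least one candidate predictor")
    X_all, y = _align(metrics, slavery, exclusions)
    rows, fits = [], {}
    for r in range(1, len(candidates) + 1):
        for subset in combinations(candidates, r):
            try:
                fit = fit_ols(y, X_all[list(subset)])
            except InputError as exc:
                logger.warning("subset %s skipped: %s", subset, exc)
                continue
            fits[subset] = fit
            rows.append(
                {
                    "predictors": "+".join(subset),
                    "n_predictors": r,
                    "aicc": fit.aicc,
                    "r2": fit.r2,
                    "f_pvalue": fit.f_pvalue,
                }
            )
    if not fits:
        raise InputError("no predictor subset produced a full-rank fit")
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    best_subset = min(fits, key=lambda s: fits[s].aicc)
    return fits[best_subset], table


def _r2_lstsq(X: np.ndarray, y: np.ndarray) -> float | None:
    """R² via least squares; None when the fit is degenerate.

    Shared by the point estimate and every Monte Carlo refit so that a
    zero-variance perturbation reproduces the point estimate bit-for-bit.
    """
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return None
    resid = y - design @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= _ZERO_TSS:
        return None
    return 1.0 - float(np.sum(resid**2)) / tss


def point_estimate_r2(
    metrics: pd.DataFrame,
    slavery: pd.DataFrame,
    predictors: tuple[str, ...],
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS,
) -> float:
    """R² of the chosen model at the unperturbed input means."""
    X, y = _align(metrics, slavery, exclusions)
    r2 = _r2_lstsq(X[list(predictors)].to_numpy(float), y.to_numpy(float))
    if r2 is None:
        raise InputError("degenerate fit at the point estimate")
    return r2


def monte_carlo_sensitivity(
    metrics: pd.DataFrame,
    slavery: pd.DataFrame,
    predictors: tuple[str, ...],
    n_runs: int = 10_000,
    scenario: str = "all",
    seed: int = 0,
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS,
) -> MonteCarloResult:
    """Propagate input uncertainty into a distribution of model R².

    Per run, fisheries predictors are drawn Normal(mean, across-year SD)
    per country (``sd_<predictor>`` columns of ``metrics``) and prevalence
    is drawn Normal(reported value, CI half-width / 1.96), truncated at
    zero; quantities outside the scenario (``all`` | ``fisheries_only`` |
    ``slavery_only``) are held at their means. The selected model is refit
    each run and its R² recorded. Degenerate draws (rank-deficient design or
    zero response variance) are skipped and counted; a warning is logged if
    more than 1% of runs are skipped.
    """
    if scenario not in ("all", "fisheries_only", "slavery_only"):
        raise InputError(f"unknown scenario {scenario!r}")
    if n_runs < 1:
        raise InputError("n_runs must be >= 1")
    X_df, y_ser = _align(metrics, slavery, exclusions)
    X0 = X_df[list(predictors)].to_numpy(float)
    n = len(X0)

    sd_cols = [f"sd_{p}" for p in predictors]
    missing = [c for c in sd_cols if c not in metrics.columns]
    if missing:
        raise InputError(f"metrics table lacks variability columns: {missing}")
    sd_X = X_df[sd_cols].to_numpy(float)
    if np.any(~np.isfinite(sd_X)) or np.any(sd_X < 0):
        raise InputError("fisheries SDs must be finite and nonnegative")

    y0 = y_ser.to_numpy(float)
    ci = slavery.loc[y_ser.index]
    sd_y = (ci["ci95_high"].to_numpy(float) - ci["ci95_low"].to_numpy(float)) / 2.0 / 1.96
    if np.any(sd_y < 0):
        raise InputError("inverted confidence intervals give negative slavery SDs")

    perturb_fish = scenario in ("all", "fisheries_only")
    perturb_slav = scenario in ("all", "slavery_only")

    rng = np.random.default_rng(seed)
    r2s = np.empty(n_runs)
    n_skipped = 0
    kept = 0
    for _ in range(n_runs):
        X = X0 + sd_X * rng.standard_normal(X0.shape) if perturb_fish else X0
        y = np.maximum(y0 + sd_y * rng.standard_normal(n), 0.0) if perturb_slav else y0
        r2 = _r2_lstsq(X, y)
        if r2 is None:
            n_skipped += 1
            continue
        r2s[kept] = r2
        kept += 1
    r2s = r2s[:kept]
    if n_skipped > 0.01 * n_runs:
        logger.warning("%d of %d Monte Carlo runs skipped as degenerate", n_skipped, n_runs)
    if kept == 0:
        raise UndefinedResultError("every Monte Carlo run was degenerate")
    return MonteCarloResult(
        scenario=scenario,
        r2=r2s,
        median_r2=float(np.median(r2s)),
        seed=seed,
        n_runs=n_runs,
        n_skipped=n_skipped,
    )


def fitted_vs_observed(fit: RegressionFit, metrics: pd.DataFrame, slavery: pd.DataFrame,
                       exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS) -> pd.DataFrame:
    """Observed and model-predicted prevalence per country, for plotting."""
    X, y = _align(metrics, slavery, exclusions)
    pred = np.full(len(X), fit.coefficients["intercept"], dtype=float)
    for name in fit.predictors:
        pred += fit.coefficients[name] * X[name].to_numpy(float)
    return pd.DataFrame({"observed": y.to_numpy(float), "predicted": pred}, index=X.index)
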