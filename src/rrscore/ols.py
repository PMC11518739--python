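"""Per-outcome ordinary-least-squares baselines.

The comparison arm: 13 independent OLS regressions, one per outcome
measure, each trained on every visit where its own outcome is observed.
Nominal and ordinal predictors are dummy-encoded (reference = lowest
category, ``n - 1`` indicator columns for ``n`` categories), real-valued
predictors standardized on the training rows, and an intercept included.
Coefficient significance uses t-tests with a Bonferroni-corrected 0.05
threshold; by default the correction pools the coefficient tests of all
13 models ("the number of tests performed"), with a per-model option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocessing import (
    OUTCOME_NAMES,
    DesignMatrix,
    Standardizer,
    select_visits,
)

__all__ = ["OLSFit", "encode_dummy", "fit_all_ols", "predict_ols",
           "bonferroni", "pooled_training_sd", "coefficient_table"]


def encode_dummy(table: pd.DataFrame, predictor_specs,
                 standardizer: Standardizer | None = None) -> DesignMatrix:
    """Dummy/standardized predictor encoding for the OLS models.

    Categorical (binary and ordinal) predictors become ``n_levels - 1``
    indicator columns against the lowest category as reference; continuous
    predictors are standardized with training parameters; an intercept
    column is appended last.
    """
    cont = [s.name for s in predictor_specs if s.kind == "continuous"]
    if standardizer is None:
        standardizer = Standardizer().fit(table, cont)
    std = standardizer.transform(table[cont]) if cont else None
    values = pd.DataFrame(index=table.index)
    encodings: dict[str, str] = {}
    for spec in predictor_specs:
        if spec.kind == "continuous":
            if spec.name in standardizer.excluded:
                continue
            values[spec.name] = std[spec.name]
            encodings[spec.name] = "standardized-continuous"
            continue
        n_cat = 2 if spec.kind == "binary" else spec.n_levels
        codes = table[spec.name].to_numpy(dtype=float)
        valid = np.isfinite(codes)
        if np.any((codes[valid] < 0) | (codes[valid] > n_cat - 1)):
            raise ValueError(
                f"predictor {spec.name!r} has categories outside 0..{n_cat - 1}"
            )
        for level in range(1, n_cat):
            col = f"{spec.name}[{level}]"
            x = np.where(valid, (codes == level).astype(float), np.nan)
            values[col] = x
            encodings[col] = "dummy-column"
    values["intercept"] = 1.0
    encodings["intercept"] = "intercept"
    return DesignMatrix(values=values, encodings=encodings, n_levels={},
                        standardizer=standardizer)


@dataclass
class OLSFit:
    """One fitted per-outcome regression with its test statistics."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n_train: int
    mse_train: float
    columns: list[str]


def fit_all_ols(design: DesignMatrix, outcomes: pd.DataFrame,
                outcome_names: list[str] | None = None) -> list[OLSFit]:
    """Fit one OLS model per outcome on that outcome's own row set.

    Each model keeps all rows where its outcome is observed (maximizing
    data per model, so the 13 models see differently sized datasets) and
    minimizes squared error.
    """
    names = outcome_names or OUTCOME_NAMES
    fits = []
    X_all = design.values
    for name in names:
        rows = select_visits(outcomes, name) if name in OUTCOME_NAMES else \
            outcomes.index[outcomes[name].notna()]
        X = X_all.loc[rows]
        y = outcomes.loc[rows, name]
        complete = X.notna().all(axis=1)
        X, y = X[complete], y[complete]
        if len(X) <= X.shape[1]:
            raise ValueError(
                f"outcome {name!r}: {len(X)} rows for {X.shape[1]} coefficients "
                "(rank deficient)"
            )
        res = sm.OLS(y.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
        cols = list(X.columns)
        fits.append(OLSFit(
            outcome=name,
            params=pd.Series(res.params, index=cols),
            bse=pd.Series(res.bse, index=cols),
            tvalues=pd.Series(res.tvalues, index=cols),
            pvalues=pd.Series(res.pvalues, index=cols),
            n_train=int(res.nobs),
            mse_train=float(np.mean(res.resid ** 2)),
            columns=cols,
        ))
    return fits


def predict_ols(fit: OLSFit, design: DesignMatrix) -> pd.Series:
    """Linear predictor (with intercept) on rows encoded with training metadata."""
    X = design.values
    if list(X.columns) != fit.columns:
        raise ValueError(
            f"design columns do not match the fit for outcome {fit.outcome!r}"
        )
    return pd.Series(X.to_numpy(dtype=float) @ fit.params.to_numpy(),
                     index=X.index, name=fit.outcome)


def bonferroni(fits: list[OLSFit], alpha: float = 0.05,
               scope: str = "all", include_intercept: bool = False) -> pd.DataFrame:
    """Bonferroni-corrected coefficient significance across the OLS models.

    ``scope="all"`` divides alpha by the total number of coefficient tests
    performed across all models (conservative); ``scope="per_model"``
    corrects within each model only.
    """
    rows = []
    for fit in fits:
        for term in fit.columns:
            if term == "intercept" and not include_intercept:
                continue
            rows.append({"outcome": fit.outcome, "term": term,
                         "estimate": fit.params[term], "se": fit.bse[term],
                         "t": fit.tvalues[term], "p": fit.pvalues[term]})
    table = pd.DataFrame(rows)
    if scope == "all":
        n_tests = len(table)
        table["n_tests"] = n_tests
    elif scope == "per_model":
        table["n_tests"] = table.groupby("outcome")["term"].transform("size")
    else:
        raise ValueError("scope must be 'all' or 'per_model'")
    table["p_bonferroni"] = np.minimum(table["p"] * table["n_tests"], 1.0)
    table["significant"] = table["p_bonferroni"] < alpha
    return table


def coefficient_table(fits: list[OLSFit], alpha: float = 0.05,
                      scope: str = "all") -> pd.DataFrame:
    """Full coefficient export (the data behind a coefficient heat map)."""
    return bonferroni(fits, alpha=alpha, scope=scope, include_intercept=True)


def pooled_training_sd(fits: list[OLSFit]) -> float:
    """Observation-weighted pooled training RMSE across the per-outcome fits.

    This is the executable derivation of the fixed observation noise used
    by the Bayesian model (default 0.908 on standardized outcomes).
    """
    sse = sum(f.mse_train * f.n_train for f in fits)
    nobs = sum(f.n_train for f in fits)
    return float(np.sqrt(sse / nobs))
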