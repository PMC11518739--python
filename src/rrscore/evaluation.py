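"""Subject-grouped cross-validation and model comparison.

Performance is measured by a whole-variance-normalized coefficient of
determination: ``R^2 = 1 - MSE / var(y)`` where the variance is computed
over the *entire* dataset (train and test pooled), so the five fold
scores share one normalizer and remain comparable across splits.  Fold
assignment is at the subject level - all visits of one subject land in
the same fold - with 5 folds (80% train / 20% test).  The Bayesian model
is scored as the mean over posterior draws of the per-draw R^2, then
averaged across folds; OLS by its point predictions.  Fold-wise scores of
the two models are compared per outcome with a t-test (paired across the
shared folds by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ols as ols_mod
from .model import (
    PriorConfig,
    build_model,
    composite_score,
    hpd_significance,
    posterior_predictive,
    sample_posterior,
    spacing_summary,
)
from .preprocessing import (
    OUTCOME_NAMES,
    Standardizer,
    build_design,
    derive_outcomes,
    impute_predictors,
    orient_outcomes,
    select_visits,
)

__all__ = ["grouped_kfold", "r2_whole_variance", "compare_models", "CVResult",
           "run_cv", "refit_full"]


def grouped_kfold(subject_ids, k: int = 5, seed: int = 0) -> dict:
    """Randomly partition subjects into ``k`` near-equal folds.

    Returns a mapping subject -> fold index; all visits of a subject share
    its fold by construction.  Reproducible from ``seed``.
    """
    subjects = pd.unique(pd.Series(subject_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k = {k} exceeds the number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = {}
    for pos, idx in enumerate(order):
        folds[subjects[idx]] = pos % k
    return folds


def r2_whole_variance(y_true, y_pred, whole_dataset_variance: float) -> float:
    """``1 - MSE / var(whole dataset)`` over the observed cells.

    The normalizer is the outcome's variance over train and test pooled,
    not the test cells, so the score can exceed classical test-set R^2 and
    is negative whenever the prediction is worse than the whole-dataset
    mean.
    """
    if whole_dataset_variance <= 0:
        raise ValueError("whole-dataset variance must be positive")
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    obs = np.isfinite(y_true)
    if not obs.any():
        raise ValueError("no observed cells to evaluate")
    mse = float(np.mean((y_true[obs] - y_pred[obs]) ** 2))
    return 1.0 - mse / whole_dataset_variance


def compare_models(scores: pd.DataFrame, model_a: str = "rrr",
                   model_b: str = "ols", paired: bool = True) -> pd.DataFrame:
    """Per-outcome t-test of fold-wise R^2 between two models.

    Folds are shared between the models, so the default test is paired
    across folds; ``paired=False`` gives the two-sample variant.
    Zero-variance inputs are flagged as degenerate instead of crashing
    (identical score vectors give t = 0, p = 1).
    """
    out = []
    for outcome, grp in scores.groupby("outcome", sort=False):
        a = grp[grp["model"] == model_a].sort_values("fold")["r2"].to_numpy()
        b = grp[grp["model"] == model_b].sort_values("fold")["r2"].to_numpy()
        if len(a) != len(b) or len(a) == 0:
            raise ValueError(f"fold mismatch between models for outcome {outcome!r}")
        diff = a - b
        degenerate = False
        if paired:
            if np.allclose(diff, 0.0):
                t, p, degenerate = 0.0, 1.0, True
            elif np.isclose(np.std(diff, ddof=1), 0.0):
                t = np.inf * np.sign(diff.mean())
                p, degenerate = 0.0, True
            else:
                t, p = stats.ttest_rel(a, b)
        else:
            if np.isclose(np.std(a, ddof=1), 0.0) and np.isclose(np.std(b, ddof=1), 0.0):
                degenerate = True
                t, p = (0.0, 1.0) if np.allclose(a, b) else (np.inf * np.sign(diff.mean()), 0.0)
            else:
                t, p = stats.ttest_ind(a, b)
        out.append({"outcome": outcome, "mean_diff": float(diff.mean()),
                    "t": float(t), "p": float(p), "degenerate": degenerate})
    return pd.DataFrame(out)


@dataclass
class CVResult:
    """Fold assignments and per-fold, per-outcome, per-model scores."""

    fold_of: dict
    scores: pd.DataFrame          # model, outcome, fold, r2, n_cells
    k: int
    seed: int
    extras: dict = field(default_factory=dict)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per model and outcome: mean fold R^2 and t-based CI half-width."""
        rows = []
        for (model, outcome), grp in self.scores.groupby(["model", "outcome"],
                                                         sort=False):
            r2 = grp["r2"].to_numpy()
            half = 0.0
            if len(r2) > 1 and np.std(r2, ddof=1) > 0:
                half = stats.t.ppf(0.5 + level / 2, len(r2) - 1) \
                    * np.std(r2, ddof=1) / np.sqrt(len(r2))
            rows.append({"model": model, "outcome": outcome,
                         "mean_r2": float(np.mean(r2)),
                         "ci_half_width": float(half), "n_folds": len(r2)})
        return pd.DataFrame(rows)

    def comparison(self, paired: bool = True) -> pd.DataFrame:
        return compare_models(self.scores, paired=paired)


def _prepare(table: pd.DataFrame, predictor_specs):
    """Impute predictors, derive and orient outcomes (fold-independent steps)."""
    pred_cols = [s.name for s in predictor_specs]
    imputed, exclusions = impute_predictors(table, pred_cols)
    imputed = imputed.reset_index(drop=True)
    outcomes = orient_outcomes(derive_outcomes(imputed))
    return imputed, outcomes, exclusions


def run_cv(table: pd.DataFrame, predictor_specs, k: int = 5, seed: int = 0,
           priors: PriorConfig | None = None, chains: int = 2,
           burn_in: int = 2000, retained: int = 500,
           models: tuple[str, ...] = ("rrr", "ols")) -> CVResult:
    """Grouped k-fold evaluation of the Bayesian RRR against per-outcome OLS.

    Both models are scored on exactly the same observed test cells per
    outcome and fold; outcome and continuous-predictor standardization is
    refit on each fold's training rows, and the R^2 normalizer is the
    outcome's variance over all rows on that fold's standardized scale.
    """
    priors = priors or PriorConfig()
    imputed, outcomes, exclusions = _prepare(table, predictor_specs)
    fold_of = grouped_kfold(imputed["subject_id"], k=k, seed=seed)
    fold_idx = imputed["subject_id"].map(fold_of).to_numpy()

    cont_cols = [s.name for s in predictor_specs if s.kind == "continuous"]
    records = []
    for f in range(k):
        test_rows = imputed.index[fold_idx == f]
        train_rows = imputed.index[fold_idx != f]
        std = Standardizer().fit(
            pd.concat([imputed.loc[train_rows, cont_cols],
                       outcomes.loc[train_rows]], axis=1),
            cont_cols + list(OUTCOME_NAMES),
        )
        y_std = std.transform(outcomes)
        whole_var = {
            name: float(np.nanvar(y_std[name].to_numpy(), ddof=0))
            for name in OUTCOME_NAMES
        }

        if "ols" in models:
            design_train = ols_mod.encode_dummy(imputed.loc[train_rows],
                                                predictor_specs, std)
            design_test = ols_mod.encode_dummy(imputed.loc[test_rows],
                                               predictor_specs, std)
            fits = ols_mod.fit_all_ols(design_train, y_std.loc[train_rows])
            for fit in fits:
                cells = y_std.loc[test_rows, fit.outcome].dropna()
                sub = ols_mod.DesignMatrix(
                    values=design_test.values.loc[cells.index],
                    encodings=design_test.encodings, n_levels={},
                    standardizer=std)
                pred = ols_mod.predict_ols(fit, sub)
                records.append({
                    "model": "ols", "outcome": fit.outcome, "fold": f,
                    "r2": r2_whole_variance(cells, pred, whole_var[fit.outcome]),
                    "n_cells": len(cells),
                })

        if "rrr" in models:
            union = select_visits(y_std.loc[train_rows], "union")
            design_train = build_design(imputed.loc[union], predictor_specs, std)
            rrr = build_model(design_train, y_std.loc[union], priors)
            post = sample_posterior(rrr, chains=chains, burn_in=burn_in,
                                    retained=retained, seed=seed + 1000 * (f + 1))
            design_test = build_design(imputed.loc[test_rows], predictor_specs, std)
            preds = posterior_predictive(post, design_test)  # (S, j_test, n)
            for o, name in enumerate(OUTCOME_NAMES):
                y_true = y_std.loc[test_rows, name].to_numpy(dtype=float)
                obs = np.isfinite(y_true)
                if not obs.any():
                    continue
                draw_r2 = [
                    r2_whole_variance(y_true[obs], preds[s][obs, o], whole_var[name])
                    for s in range(preds.shape[0])
                ]
                records.append({
                    "model": "rrr", "outcome": name, "fold": f,
                    "r2": float(np.mean(draw_r2)), "n_cells": int(obs.sum()),
                })

    scores = pd.DataFrame(records)
    return CVResult(fold_of=fold_of, scores=scores, k=k, seed=seed,
                    extras={"exclusions": exclusions})


def refit_full(table: pd.DataFrame, predictor_specs,
               priors: PriorConfig | None = None, chains: int = 2,
               burn_in: int = 2000, retained: int = 500, seed: int = 0,
               models: tuple[str, ...] = ("rrr", "ols")) -> dict:
    """Refit both arms on the complete dataset for the final coefficients.

    Returns the end products of a run: the HPD significance table and
    composite scores of the Bayesian model, the ordinal spacing summary,
    and the Bonferroni-corrected OLS coefficient tables.
    """
    priors = priors or PriorConfig()
    imputed, outcomes, exclusions = _prepare(table, predictor_specs)
    cont_cols = [s.name for s in predictor_specs if s.kind == "continuous"]
    std = Standardizer().fit(
        pd.concat([imputed[cont_cols], outcomes], axis=1),
        cont_cols + list(OUTCOME_NAMES),
    )
    y_std = std.transform(outcomes)
    artifacts: dict = {"exclusions": exclusions, "standardizer": std}

    if "ols" in models:
        design = ols_mod.encode_dummy(imputed, predictor_specs, std)
        fits = ols_mod.fit_all_ols(design, y_std)
        artifacts["ols_fits"] = fits
        artifacts["ols_coefficients"] = ols_mod.coefficient_table(fits)
        artifacts["pooled_training_sd"] = ols_mod.pooled_training_sd(fits)

    if "rrr" in models:
        union = select_visits(y_std, "union")
        design = build_design(imputed.loc[union], predictor_specs, std)
        rrr = build_model(design, y_std.loc[union], priors)
        post = sample_posterior(rrr, chains=chains, burn_in=burn_in,
                                retained=retained, seed=seed)
        theta, theta_summary = composite_score(post, design)
        artifacts["posterior"] = post
        artifacts["significance"] = hpd_significance(post)
        artifacts["composite_scores"] = theta_summary
        artifacts["spacing"] = spacing_summary(post)
        artifacts["diagnostics"] = post.diagnostics
    return artifacts
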