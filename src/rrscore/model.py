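"""Bayesian reduced-rank regression with sparse loadings and monotonic ordinals.

The model predicts an ``j x n`` centered outcome matrix ``Y`` from an
``j x m`` encoded predictor matrix ``X`` through ``k`` latent composite
scores::

    theta = X A            A: m x k, element-wise Laplace(0, b) prior (sparsity)
    Y ~ Normal(theta B^T, sigma^2)   B: n x k, lognormal(median 1, sd 0.25) prior

All entries of ``B`` are positive, so the sign of a predictor's effect on
every outcome is carried entirely by ``A``; with outcomes oriented so that
higher = worse, a positive loading marks a risk factor and a negative one
a protective factor.  The observation noise is fixed (default
``sigma = 0.908``, the pooled training RMSE of the per-outcome OLS
baselines).  Ordinal predictor columns enter through the cumulative
monotonic transform ``cmo(x, zeta)`` whose simplexes ``zeta`` carry
``Dirichlet(alpha = 1)`` priors and are inferred jointly with ``A`` and
``B``.  Missing outcome cells simply contribute nothing to the
likelihood.

Because the outcomes are centered and the model carries no intercept, the
likelihood uses the training-row-centered linear predictor
``(X - x_bar) A B^T`` (the mean of an ordinal column is recomputed per
draw from its sampled spacings); otherwise the nonzero mean of the latent
score would have to be absorbed by the uncentered binary/ordinal columns,
biasing their loadings.  The reported composite score stays
``theta = X A``.

Sampling uses the in-package NUTS implementation on the unconstrained
space: ``B = exp(u)`` with a normal prior on ``u``, and each simplex is
softmax-normalized from log-gamma-augmented coordinates (``zeta_i
proportional to exp(y_i)`` with ``p(y_i) proportional to exp(alpha y_i -
e^{y_i})``), which has an exact ``Dirichlet(alpha)`` marginal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .nuts import nuts_sample
from .preprocessing import DesignMatrix

__all__ = [
    "PriorConfig",
    "RRRModel",
    "RRRPosterior",
    "build_model",
    "sample_posterior",
    "posterior_predictive",
    "composite_score",
    "hpd_interval",
    "hpd_significance",
    "spacing_summary",
]


@dataclass
class PriorConfig:
    """Prior and structural configuration of the reduced-rank model."""

    laplace_scale: float = 1.0        # b of the Laplace prior on A
    lognormal_sd: float = 0.25        # shape of the lognormal prior on B
    observation_sd: float = 0.908     # fixed Gaussian noise sigma
    dirichlet_alpha: float = 1.0      # concentration of the spacing prior
    rank: int = 1                     # latent dimension k
    deterministic_B: bool = False     # force B = 1 (single shared predictor)
    per_outcome_sd: np.ndarray | None = None  # optional sigma per outcome

    def __post_init__(self) -> None:
        for val, name in ((self.laplace_scale, "laplace_scale"),
                          (self.lognormal_sd, "lognormal_sd"),
                          (self.observation_sd, "observation_sd"),
                          (self.dirichlet_alpha, "dirichlet_alpha")):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.deterministic_B and self.rank != 1:
            raise ValueError("deterministic_B requires rank k = 1")


class RRRModel:
    """Log-posterior (with analytic gradient) of the Bayesian RRR.

    Built from an encoded :class:`~rrscore.preprocessing.DesignMatrix` and a
    centered outcome matrix with missing cells as NaN.
    """

    def __init__(self, design: DesignMatrix, Y: pd.DataFrame, priors: PriorConfig):
        if len(design.values) != len(Y):
            raise ValueError("design matrix and outcome matrix have different row counts")
        self.priors = priors
        self.column_names = list(design.values.columns)
        self.outcome_names = list(Y.columns)
        m, n = len(self.column_names), len(self.outcome_names)
        if priors.rank > min(m, n):
            raise ValueError("rank k must satisfy k <= min(n_outcomes, n_predictors)")

        Yv = Y.to_numpy(dtype=float)
        mask = np.isfinite(Yv)
        keep = mask.any(axis=1)
        if not keep.any():
            raise ValueError("all outcome rows are fully missing")
        if not keep.all():
            warnings.warn(
                f"excluding {int((~keep).sum())} row(s) with no observed outcome"
            )
        self.row_index = Y.index[keep]
        self.Y = np.nan_to_num(Yv[keep])
        self.mask = mask[keep].astype(float)

        X = design.values.loc[self.row_index]
        self.X_base = X.to_numpy(dtype=float).copy()
        self.ordinals = []  # (column position, codes, D)
        for name in design.ordinal_columns:
            c = self.column_names.index(name)
            codes = X[name].to_numpy(dtype=int)
            D = design.n_levels[name] - 1
            self.ordinals.append((name, c, codes, D))
            self.X_base[:, c] = 0.0
        # centering Y lets the offset be omitted only if the linear predictor
        # is centered too; fixed columns are centered here, ordinal columns
        # per draw via the training exceedance fractions q_l = P(code >= l)
        self.fixed_offsets = self.X_base.mean(axis=0)
        self.X_base = self.X_base - self.fixed_offsets
        self.ordinal_q = {
            name: np.array([(codes >= l).mean() for l in range(1, D + 1)])
            for name, _, codes, D in self.ordinals
        }

        sd = priors.per_outcome_sd
        if sd is None:
            sd = np.full(n, priors.observation_sd)
        self.inv_var = 1.0 / np.asarray(sd, dtype=float) ** 2  # (n,)

        self.m, self.n, self.k = m, n, priors.rank
        self.j = self.X_base.shape[0]

    # ---- parameter vector layout -------------------------------------
    @property
    def dim(self) -> int:
        d = self.m * self.k
        if not self.priors.deterministic_B:
            d += self.n * self.k
        d += sum(D for *_, D in self.ordinals)
        return d

    def unpack(self, w: np.ndarray):
        """Split an unconstrained vector into (A, B, zetas)."""
        pos = self.m * self.k
        A = w[:pos].reshape(self.m, self.k)
        if self.priors.deterministic_B:
            B = np.ones((self.n, self.k))
        else:
            B = np.exp(w[pos:pos + self.n * self.k].reshape(self.n, self.k))
            pos += self.n * self.k
        zetas = {}
        for name, _, _, D in self.ordinals:
            y = w[pos:pos + D]
            e = np.exp(y - y.max())
            zetas[name] = e / e.sum()
            pos += D
        return A, B, zetas

    def encode_X(self, zetas: dict[str, np.ndarray],
                 X_base: np.ndarray | None = None,
                 ordinals=None, centered: bool = False) -> np.ndarray:
        """Design matrix under given simplexes (cmo applied to ordinal columns).

        With ``centered=True`` the training-row means are subtracted from
        every column (fixed columns exactly, ordinal columns through the
        training exceedance fractions), matching the likelihood's centered
        linear predictor.  ``X_base`` given for new rows must be raw.
        """
        if X_base is None:
            X = self.X_base.copy()                     # already centered
            if not centered:
                X = X + self.fixed_offsets
        else:
            X = X_base.copy()
            if centered:
                X = X - self.fixed_offsets
        for name, c, codes, D in (self.ordinals if ordinals is None else ordinals):
            table = np.concatenate([[0.0], np.cumsum(zetas[name])])
            X[:, c] = table[codes]
            if centered:
                X[:, c] -= float(zetas[name] @ self.ordinal_q[name])
        return X

    # ---- log posterior and gradient ----------------------------------
    def logp_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        pos = self.m * self.k
        A = w[:pos].reshape(self.m, self.k)
        if pr.deterministic_B:
            u = None
            B = np.ones((self.n, self.k))
        else:
            u = w[pos:pos + self.n * self.k].reshape(self.n, self.k)
            B = np.exp(u)
            pos += self.n * self.k
        ys, zetas = [], {}
        for name, _, _, D in self.ordinals:
            y = w[pos:pos + D]
            e = np.exp(y - y.max())
            zetas[name] = e / e.sum()
            ys.append(y)
            pos += D

        X = self.encode_X(zetas, centered=True)
        theta = X @ A                      # (j, k)
        pred = theta @ B.T                 # (j, n)
        resid = (self.Y - pred) * self.mask
        G = resid * self.inv_var           # d loglik / d pred
        logp = -0.5 * float(np.sum(resid * G))

        GB = G @ B                         # (j, k)
        grad_A = X.T @ GB
        # Laplace(0, b) prior on A (subgradient at 0)
        logp += -np.abs(A).sum() / pr.laplace_scale
        grad_A += -np.sign(A) / pr.laplace_scale

        grads = [grad_A.ravel()]
        if not pr.deterministic_B:
            grad_B = G.T @ theta           # (n, k)
            grad_u = grad_B * B
            # lognormal(median 1) prior: normal on u
            logp += -0.5 * float(np.sum(u * u)) / pr.lognormal_sd ** 2
            grad_u += -u / pr.lognormal_sd ** 2
            grads.append(grad_u.ravel())

        for (name, c, codes, D), y in zip(self.ordinals, ys):
            zeta = zetas[name]
            gcol = GB @ A[c]               # (j,) d loglik / d X[:, c]
            sums = np.bincount(codes, weights=gcol, minlength=D + 1)
            # dL/dzeta_l = sum over rows with code >= l, minus the centering
            # term q_l * sum(g) from the per-draw training mean
            dzeta = np.cumsum(sums[::-1])[::-1][1:] \
                - self.ordinal_q[name] * gcol.sum()
            # softmax Jacobian
            grad_y = zeta * (dzeta - np.dot(zeta, dzeta))
            # log-gamma augmentation: p(y_i) prop exp(alpha*y_i - e^{y_i})
            logp += float(np.sum(pr.dirichlet_alpha * y - np.exp(y)))
            grad_y += pr.dirichlet_alpha - np.exp(y)
            grads.append(grad_y)

        return logp, np.concatenate(grads)

    def initial_point(self, rng) -> np.ndarray:
        return 0.1 * rng.standard_normal(self.dim)


def build_model(design: DesignMatrix, Y: pd.DataFrame,
                priors: PriorConfig | None = None) -> RRRModel:
    """Assemble the Bayesian RRR from encoded predictors and centered outcomes."""
    return RRRModel(design, Y, priors or PriorConfig())


@dataclass
class RRRPosterior:
    """Posterior draws of the reduced-rank model and sampler diagnostics."""

    A: np.ndarray                       # (S, m, k)
    B: np.ndarray                       # (S, n, k)
    zetas: dict[str, np.ndarray]        # name -> (S, D)
    theta: np.ndarray                   # (S, j, k) latent scores on training rows
    column_names: list[str]
    outcome_names: list[str]
    model: RRRModel
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.A.shape[0]


def sample_posterior(model: RRRModel, chains: int = 2, burn_in: int = 2000,
                     retained: int = 500, seed: int = 0,
                     max_treedepth: int = 10,
                     divergence_warn_fraction: float = 0.05) -> RRRPosterior:
    """Draw from the posterior with NUTS.

    Defaults follow the reference run: two chains, 2000 burn-in and 500
    retained draws each, i.e. 1000 posterior draws per parameter.  Reduced
    settings (smaller ``burn_in``/``retained``) are appropriate for tests.
    """
    rng = np.random.default_rng(seed)
    chain_draws, total_div = [], 0
    step_sizes = []
    for _ in range(chains):
        x0 = model.initial_point(rng)
        draws, stats = nuts_sample(
            model.logp_grad, x0, n_warmup=burn_in, n_draws=retained,
            seed=rng.integers(2**31 - 1), max_treedepth=max_treedepth,
        )
        chain_draws.append(draws)
        total_div += stats.divergences
        step_sizes.append(stats.step_size)

    stacked = np.concatenate(chain_draws, axis=0)   # (chains*retained, dim)
    S = stacked.shape[0]
    A = np.empty((S, model.m, model.k))
    B = np.empty((S, model.n, model.k))
    zetas = {name: np.empty((S, D)) for name, _, _, D in model.ordinals}
    theta = np.empty((S, model.j, model.k))
    for s in range(S):
        a, b, z = model.unpack(stacked[s])
        A[s], B[s] = a, b
        for name in zetas:
            zetas[name][s] = z[name]
        theta[s] = model.encode_X(z) @ a

    if chains >= 2:
        rhat = az.rhat(az.convert_to_dataset(np.stack(chain_draws)))["x"].to_numpy()
        max_rhat = float(np.nanmax(rhat))
    else:  # split-Rhat needs at least two chains
        rhat = np.full(stacked.shape[1], np.nan)
        max_rhat = float("nan")
    frac_div = total_div / max(S, 1)
    if frac_div > divergence_warn_fraction:
        warnings.warn(
            f"{total_div} divergent transitions ({frac_div:.1%} of draws); "
            f"max split-Rhat {max_rhat:.3f}"
        )
    diagnostics = {
        "divergences": int(total_div),
        "divergence_fraction": float(frac_div),
        "rhat": rhat,
        "max_rhat": max_rhat,
        "step_sizes": step_sizes,
        "chains": chains,
        "burn_in": burn_in,
        "retained": retained,
    }
    return RRRPosterior(A=A, B=B, zetas=zetas, theta=theta,
                        column_names=model.column_names,
                        outcome_names=model.outcome_names,
                        model=model, diagnostics=diagnostics)


def _encode_new(posterior: RRRPosterior, design: DesignMatrix) -> tuple[np.ndarray, list]:
    if list(design.values.columns) != posterior.column_names:
        raise ValueError("design columns do not match the fitted model")
    X_base = design.values.to_numpy(dtype=float).copy()
    ordinals = []
    for name, c, _, D in posterior.model.ordinals:
        codes = design.values[name].to_numpy(dtype=int)
        ordinals.append((name, c, codes, D))
        X_base[:, c] = 0.0
    return X_base, ordinals


def posterior_predictive(posterior: RRRPosterior, design: DesignMatrix,
                         include_noise: bool = False, seed: int = 0) -> np.ndarray:
    """Per-draw predictions ``X A B^T`` on new rows, shape ``(S, j_new, n)``.

    With ``include_noise`` the fixed Gaussian observation noise is added,
    giving draws from the posterior predictive distribution; evaluation
    uses the noiseless mean.
    """
    X_base, ordinals = _encode_new(posterior, design)
    S = posterior.n_draws
    out = np.empty((S, X_base.shape[0], len(posterior.outcome_names)))
    for s in range(S):
        z = {name: posterior.zetas[name][s] for name in posterior.zetas}
        X = posterior.model.encode_X(z, X_base=X_base, ordinals=ordinals,
                                     centered=True)
        out[s] = (X @ posterior.A[s]) @ posterior.B[s].T
    if include_noise:
        rng = np.random.default_rng(seed)
        sd = 1.0 / np.sqrt(posterior.model.inv_var)
        out = out + rng.standard_normal(out.shape) * sd
    return out


def composite_score(posterior: RRRPosterior, design: DesignMatrix,
                    level: float = 0.95) -> tuple[np.ndarray, pd.DataFrame]:
    """Latent composite scores ``theta = X A`` on new rows.

    Returns the per-draw scores ``(S, j_new, k)`` and a per-visit summary
    (posterior mean and HPD bounds per latent factor).
    """
    X_base, ordinals = _encode_new(posterior, design)
    S = posterior.n_draws
    theta = np.empty((S, X_base.shape[0], posterior.A.shape[2]))
    for s in range(S):
        z = {name: posterior.zetas[name][s] for name in posterior.zetas}
        X = posterior.model.encode_X(z, X_base=X_base, ordinals=ordinals)
        theta[s] = X @ posterior.A[s]
    rows = []
    for i in range(theta.shape[1]):
        for f in range(theta.shape[2]):
            lo, hi = hpd_interval(theta[:, i, f], level)
            rows.append({"row": design.values.index[i], "factor": f,
                         "mean": theta[:, i, f].mean(), "hpd_low": lo,
                         "hpd_high": hi})
    return theta, pd.DataFrame(rows)


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``level`` of the draws (sorted-window HPD)."""
    draws = np.sort(np.asarray(draws, dtype=float))
    S = draws.size
    if S < 2:
        return float(draws[0]), float(draws[0])
    window = max(1, int(np.ceil(level * S)))
    window = min(window, S)
    widths = draws[window - 1:] - draws[:S - window + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + window - 1])


def hpd_significance(posterior: RRRPosterior, level: float = 0.95) -> pd.DataFrame:
    """Per-predictor effect summary with the HPD-excludes-zero significance rule.

    Under the higher-is-worse outcome orientation and positive ``B``, a
    positive posterior-mean loading is a risk factor, a negative one
    protective.
    """
    rows = []
    for f in range(posterior.A.shape[2]):
        for c, name in enumerate(posterior.column_names):
            draws = posterior.A[:, c, f]
            lo, hi = hpd_interval(draws, level)
            mean = float(draws.mean())
            significant = bool(lo > 0.0 or hi < 0.0)
            rows.append({
                "predictor": name,
                "factor": f,
                "mean": mean,
                "hpd_low": lo,
                "hpd_high": hi,
                "significant": significant,
                "direction": "risk" if mean > 0 else ("protective" if mean < 0 else "null"),
            })
    return pd.DataFrame(rows)


def spacing_summary(posterior: RRRPosterior, level: float = 0.95) -> pd.DataFrame:
    """Posterior spacings of ordinal predictors scaled by their effect size.

    For each category transition ``i -> i+1`` of each ordinal predictor the
    summarized quantity is ``zeta_i * A`` per draw (the contribution of that
    transition to the composite score), with mean and HPD bounds.
    """
    rows = []
    for name, c, _, D in posterior.model.ordinals:
        for f in range(posterior.A.shape[2]):
            effect = posterior.A[:, c, f]
            for i in range(D):
                draws = posterior.zetas[name][:, i] * effect
                lo, hi = hpd_interval(draws, level)
                rows.append({
                    "predictor": name,
                    "factor": f,
                    "transition": f"{i}->{i + 1}",
                    "mean": float(draws.mean()),
                    "hpd_low": lo,
                    "hpd_high": hi,
                })
    return pd.DataFrame(rows)
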