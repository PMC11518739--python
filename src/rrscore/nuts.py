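"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained implementation of NUTS (dynamic-length Hamiltonian Monte
Carlo with the no-u-turn termination criterion and multinomial sampling
across the trajectory), with dual-averaging step-size adaptation and
diagonal mass-matrix estimation during warmup.  It needs only a function
returning the log posterior density and its gradient on an unconstrained
parameter vector.

Warmup schedule: the first 15% of warmup adapts the step size under an
identity metric; draws from the middle window (15%-75%) estimate the
diagonal metric from parameter variances; the final 25% re-adapts the step
size under the new metric.  A leapfrog step whose energy error exceeds
1000 is recorded as a divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["nuts_sample", "ChainStats"]

_MAX_DELTA_H = 1000.0


@dataclass
class ChainStats:
    """Per-chain sampler diagnostics."""

    divergences: int = 0
    step_size: float = float("nan")
    mean_accept: float = float("nan")
    tree_depths: list = field(default_factory=list)


class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance delta)."""

    def __init__(self, eps0: float, delta: float = 0.8, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.delta, self.gamma, self.t0, self.kappa = delta, gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_stat: float) -> float:
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.delta - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    """One leapfrog step; carries the gradient so each step costs one evaluation."""
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    logp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _hamiltonian(logp, p, inv_mass):
    return logp - 0.5 * np.dot(p, inv_mass * p)


def _find_initial_step(logp_grad, x0, inv_mass, rng):
    eps = 1.0
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    logp0, grad0 = logp_grad(x0)
    h0 = _hamiltonian(logp0, p0, inv_mass)
    x1, p1, logp1, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass)
    dh = _hamiltonian(logp1, p1, inv_mass) - h0
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0 ** direction
        x1, p1, logp1, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass)
        dh = _hamiltonian(logp1, p1, inv_mass) - h0
        if not np.isfinite(dh):
            dh = -np.inf
        if direction * dh <= direction * np.log(0.5):
            break
    return max(eps, 1e-8)


class _Tree:
    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "log_w", "n_div", "sum_accept", "n_leaf", "turning")

    def __init__(self, x_minus, p_minus, g_minus, x_plus, p_plus, g_plus,
                 x_prop, log_w, n_div, sum_accept, n_leaf, turning):
        self.x_minus, self.p_minus, self.g_minus = x_minus, p_minus, g_minus
        self.x_plus, self.p_plus, self.g_plus = x_plus, p_plus, g_plus
        self.x_prop, self.log_w = x_prop, log_w
        self.n_div, self.sum_accept, self.n_leaf = n_div, sum_accept, n_leaf
        self.turning = turning


def _uturn(x_minus, p_minus, x_plus, p_plus, inv_mass) -> bool:
    dx = x_plus - x_minus
    return (np.dot(dx, inv_mass * p_minus) < 0) or (np.dot(dx, inv_mass * p_plus) < 0)


def _build_tree(logp_grad, x, p, grad, direction, depth, eps, h0, inv_mass, rng):
    if depth == 0:
        x1, p1, logp1, g1 = _leapfrog(logp_grad, x, p, grad, direction * eps,
                                      inv_mass)
        h1 = _hamiltonian(logp1, p1, inv_mass)
        dh = h1 - h0
        if not np.isfinite(dh):
            dh = -np.inf
        divergent = dh < -_MAX_DELTA_H
        accept = min(1.0, float(np.exp(min(dh, 0.0))))
        log_w = -np.inf if divergent else dh
        return _Tree(x1, p1, g1, x1, p1, g1, x1, log_w, int(divergent), accept,
                     1, divergent)

    inner = _build_tree(logp_grad, x, p, grad, direction, depth - 1, eps, h0,
                        inv_mass, rng)
    if inner.turning:
        return inner
    if direction == 1:
        outer = _build_tree(logp_grad, inner.x_plus, inner.p_plus, inner.g_plus,
                            direction, depth - 1, eps, h0, inv_mass, rng)
        x_minus, p_minus, g_minus = inner.x_minus, inner.p_minus, inner.g_minus
        x_plus, p_plus, g_plus = outer.x_plus, outer.p_plus, outer.g_plus
    else:
        outer = _build_tree(logp_grad, inner.x_minus, inner.p_minus, inner.g_minus,
                            direction, depth - 1, eps, h0, inv_mass, rng)
        x_minus, p_minus, g_minus = outer.x_minus, outer.p_minus, outer.g_minus
        x_plus, p_plus, g_plus = inner.x_plus, inner.p_plus, inner.g_plus

    log_w = np.logaddexp(inner.log_w, outer.log_w)
    # multinomial sampling among the subtree leaves
    if np.isfinite(outer.log_w) and np.log(rng.random()) < outer.log_w - log_w:
        x_prop = outer.x_prop
    else:
        x_prop = inner.x_prop
    turning = (outer.turning
               or _uturn(x_minus, p_minus, x_plus, p_plus, inv_mass))
    return _Tree(x_minus, p_minus, g_minus, x_plus, p_plus, g_plus, x_prop, log_w,
                 inner.n_div + outer.n_div, inner.sum_accept + outer.sum_accept,
                 inner.n_leaf + outer.n_leaf, turning)


def _nuts_step(logp_grad, x, eps, inv_mass, rng, max_treedepth):
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    logp0, grad0 = logp_grad(x)
    h0 = _hamiltonian(logp0, p0, inv_mass)

    x_minus, p_minus, g_minus = x.copy(), p0.copy(), grad0.copy()
    x_plus, p_plus, g_plus = x.copy(), p0.copy(), grad0.copy()
    x_sample = x
    log_w = 0.0  # weight of the initial point relative to itself
    n_div = 0
    sum_accept, n_leaf = 0.0, 0
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, x_plus, p_plus, g_plus, 1, depth, eps,
                              h0, inv_mass, rng)
            x_plus, p_plus, g_plus = sub.x_plus, sub.p_plus, sub.g_plus
        else:
            sub = _build_tree(logp_grad, x_minus, p_minus, g_minus, -1, depth,
                              eps, h0, inv_mass, rng)
            x_minus, p_minus, g_minus = sub.x_minus, sub.p_minus, sub.g_minus
        n_div += sub.n_div
        sum_accept += sub.sum_accept
        n_leaf += sub.n_leaf
        if sub.turning:
            break
        # biased progressive sampling: favor the new subtree
        if np.isfinite(sub.log_w) and np.log(rng.random()) < sub.log_w - log_w:
            x_sample = sub.x_prop
        log_w = np.logaddexp(log_w, sub.log_w)
        depth += 1
        if _uturn(x_minus, p_minus, x_plus, p_plus, inv_mass):
            break
    accept_stat = sum_accept / max(n_leaf, 1)
    return x_sample, accept_stat, n_div, depth


def nuts_sample(logp_grad, x0, n_warmup: int, n_draws: int, seed,
                max_treedepth: int = 10, target_accept: float = 0.8,
                ) -> tuple[np.ndarray, ChainStats]:
    """Run one NUTS chain and return post-warmup draws.

    Parameters
    ----------
    logp_grad : callable
        ``x -> (logp, grad)`` on the unconstrained space.
    x0 : array
        Initial position.
    n_warmup, n_draws : int
        Burn-in iterations (discarded, used for adaptation) and retained draws.
    seed : int or Generator
        Randomness source.

    Returns
    -------
    (draws, stats) with ``draws`` of shape ``(n_draws, dim)``.
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    dim = x.size
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    averager = _DualAveraging(eps, delta=target_accept)

    phase1 = max(1, int(0.15 * n_warmup))
    phase2 = max(phase1 + 1, int(0.75 * n_warmup))
    window: list[np.ndarray] = []

    stats = ChainStats()
    for i in range(n_warmup):
        x, accept_stat, n_div, _ = _nuts_step(logp_grad, x, eps, inv_mass, rng,
                                              max_treedepth)
        eps = averager.update(accept_stat)
        if phase1 <= i < phase2:
            window.append(x.copy())
        if i == phase2 - 1 and len(window) >= 10:
            var = np.var(np.asarray(window), axis=0)
            # regularize towards unity like Stan's windowed estimator
            n = len(window)
            inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
            inv_mass = np.maximum(inv_mass, 1e-10)
            eps = _find_initial_step(logp_grad, x, inv_mass, rng)
            averager = _DualAveraging(eps, delta=target_accept)
    eps = averager.adapted if n_warmup > 0 else eps

    draws = np.empty((n_draws, dim))
    accepts = []
    for s in range(n_draws):
        x, accept_stat, n_div, depth = _nuts_step(logp_grad, x, eps, inv_mass,
                                                  rng, max_treedepth)
        draws[s] = x
        stats.divergences += n_div
        stats.tree_depths.append(depth)
        accepts.append(accept_stat)
    stats.step_size = float(eps)
    stats.mean_accept = float(np.mean(accepts)) if accepts else float("nan")
    return draws, stats
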