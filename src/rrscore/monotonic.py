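"""Cumulative monotonic encoding of ordinal predictors.

An ordinal predictor with categories ``0, ..., D`` is encoded through a
simplex vector ``zeta`` of length ``D`` whose entries are the normalized
distances between adjacent categories::

    cmo(x, zeta) = sum_{i=1}^{x} zeta_i          in [0, 1]
    mo(x, zeta)  = D * cmo(x, zeta)              in [0, D]

The encoding is monotone in ``x`` by construction, while the spacing of
categories is free; sign and overall magnitude of the effect live in the
regression coefficient, not in the encoding.  A ``Dirichlet(alpha)`` prior
on ``zeta`` with ``alpha = 1`` is uniform on the simplex, so a priori each
spacing has mean ``1/D`` (a linear trend) with wide variation around it.

The same machinery is used for genetic dose variables (0/1/2 risk alleles):
a free spacing lets the fit interpolate between dominant (0 vs 1),
additive (0 vs 1 vs 2) and recessive (0 vs 2) effect shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MonotonicEncoding",
    "cmo",
    "mo",
    "encode_ordinal_column",
    "sample_zeta",
]

_SIMPLEX_TOL = 1e-10


def _validate_zeta(zeta: np.ndarray) -> np.ndarray:
    zeta = np.asarray(zeta, dtype=float)
    if zeta.ndim != 1 or zeta.size < 1:
        raise ValueError("zeta must be a 1-D simplex vector")
    if np.any(zeta < -_SIMPLEX_TOL) or np.any(zeta > 1 + _SIMPLEX_TOL):
        raise ValueError("zeta entries must lie in [0, 1]")
    if abs(zeta.sum() - 1.0) > 1e-8:
        raise ValueError(f"zeta must sum to 1, got {zeta.sum()!r}")
    return zeta


def cmo(x, zeta) -> np.ndarray | float:
    """Cumulative monotonic transform ``cmo(x, zeta) = sum_{i<=x} zeta_i``.

    Parameters
    ----------
    x : int or array of int
        Ordinal code(s) in ``{0, ..., D}`` where ``D = len(zeta)``.
    zeta : array
        Simplex vector of normalized category distances.

    Returns
    -------
    Value(s) in ``[0, 1]``; ``cmo(0) = 0`` and ``cmo(D) = 1``.
    """
    zeta = _validate_zeta(zeta)
    D = zeta.size
    codes = np.asarray(x)
    if not np.issubdtype(codes.dtype, np.integer):
        if not np.all(codes == np.floor(codes)):
            raise ValueError("ordinal codes must be integers")
        codes = codes.astype(int)
    if np.any(codes < 0) or np.any(codes > D):
        raise ValueError(f"ordinal codes must lie in 0..{D}")
    table = np.concatenate([[0.0], np.cumsum(zeta)])
    out = table[codes]
    return float(out) if np.isscalar(x) else out


def mo(x, zeta) -> np.ndarray | float:
    """Monotonic transform ``mo = D * cmo`` mapping ``{0..D}`` into ``[0, D]``.

    Kept for reference: the factor ``D`` is redundant with the regression
    coefficient, which is why the model uses :func:`cmo`.
    """
    zeta = _validate_zeta(zeta)
    return zeta.size * cmo(x, zeta)


def encode_ordinal_column(codes, zeta_draws) -> np.ndarray:
    """Encode an ordinal code column under one or many simplex draws.

    ``zeta_draws`` may be a single simplex (returns shape ``(j,)``) or a
    ``(S, D)`` stack of posterior draws (returns shape ``(S, j)``).
    """
    zeta_draws = np.asarray(zeta_draws, dtype=float)
    if zeta_draws.ndim == 1:
        return cmo(codes, zeta_draws)
    return np.stack([cmo(codes, z) for z in zeta_draws])


def sample_zeta(D: int, alpha: float = 1.0, size: int | None = None, rng=None) -> np.ndarray:
    """Draw simplex vectors from the symmetric ``Dirichlet(alpha)`` prior."""
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.dirichlet(np.full(D, float(alpha)), size=size)


@dataclass
class MonotonicEncoding:
    """Encoding state for one ordinal predictor.

    Attributes
    ----------
    name : predictor identifier.
    n_levels : number of categories ``D + 1``.
    alpha : Dirichlet concentration of the spacing prior (default 1).
    zeta : optional fixed simplex; when ``None`` the spacing is inferred.
    """

    name: str
    n_levels: int
    alpha: float = 1.0
    zeta: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("ordinal predictors need at least 2 levels")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.zeta is not None:
            self.zeta = _validate_zeta(self.zeta)
            if self.zeta.size != self.D:
                raise ValueError("zeta length must equal n_levels - 1")

    @property
    def D(self) -> int:
        """Number of inter-category distances."""
        return self.n_levels - 1

    @property
    def prior_mean_spacing(self) -> np.ndarray:
        """Prior mean of each spacing, ``alpha_i / sum(alpha) = 1/D``."""
        return np.full(self.D, 1.0 / self.D)

    def encode(self, codes) -> np.ndarray:
        if self.zeta is None:
            raise ValueError(f"no zeta fixed for ordinal predictor {self.name!r}")
        return cmo(codes, self.zeta)
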