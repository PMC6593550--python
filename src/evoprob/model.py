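"""Poisson amino-acid substitution model with discrete-Gamma rates and
invariant sites (G + I).

The Poisson (equal-input) model assigns every residue pair the same
exchange rate and uniform stationary frequencies (1/20), so its
transition probabilities have the closed form

    P(same | d) = 1/20 + (19/20) * exp(-(20/19) * d)
    P(diff | d) = (1 - P(same | d)) / 19

for an expected number of substitutions per site ``d``.  Rate
heterogeneity uses K equal-probability Gamma categories (mean 1) plus a
zero-rate invariant class of weight ``p_inv``.  Branch lengths are read
as substitutions per site averaged over the full mixture, so the Gamma
category multipliers are rescaled by 1/(1 - p_inv) to keep the mixture
mean at 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .alignment import AMINO_ACIDS

N_STATES = 20
_POISSON_BETA = N_STATES / (N_STATES - 1)  # 20/19

__all__ = ["PoissonGI", "discretize_gamma", "transition_matrix", "N_STATES"]


def discretize_gamma(alpha: float, K: int) -> np.ndarray:
    """Mean-of-slice discretisation of a mean-1 Gamma(alpha, alpha)
    distribution into ``K`` equal-probability rate categories.

    Category ``j`` gets the conditional mean of the Gamma distribution on
    its quantile slice, so the K rates average to exactly 1.
    """
    if alpha <= 0:
        raise ValueError("Gamma shape alpha must be > 0")
    if K < 1:
        raise ValueError("need at least one rate category")
    if K == 1:
        return np.ones(1)
    edges = stats.gamma.ppf(np.arange(K + 1) / K, a=alpha, scale=1.0 / alpha)
    # E[X; X <= c] for Gamma(shape a, rate a) is P(a+1, a*c), regularized
    cum = np.empty(K + 1)
    cum[0] = 0.0
    cum[-1] = 1.0
    cum[1:-1] = special.gammainc(alpha + 1.0, alpha * edges[1:-1])
    return K * np.diff(cum)


@dataclass(frozen=True)
class PoissonGI:
    """Poisson+G+I model configuration.

    Parameters
    ----------
    alpha:
        Gamma shape; small values mean strong among-site rate variation.
    p_inv:
        Proportion of invariant (rate-0) sites, in [0, 1).
    K:
        Number of discrete Gamma categories (5 in routine use).
    """

    alpha: float = 1.0
    p_inv: float = 0.0
    K: int = 5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def category_rates(self) -> np.ndarray:
        """Mean-1 Gamma category rates (before the invariant-class rescale)."""
        return discretize_gamma(self.alpha, self.K)

    @property
    def rate_multipliers(self) -> np.ndarray:
        """Per-category branch-length multipliers; scaled by 1/(1-p_inv)
        so the full mixture (including the rate-0 invariant class) has
        mean rate 1."""
        return self.category_rates / (1.0 - self.p_inv)

    @property
    def category_weight(self) -> float:
        """Mixture weight of each Gamma category."""
        return (1.0 - self.p_inv) / self.K

    # -- serialisation ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"model": "poisson_gi", "alpha": self.alpha,
                           "p_inv": self.p_inv, "K": self.K})

    @classmethod
    def from_json(cls, text: str) -> "PoissonGI":
        d = json.loads(text)
        return cls(alpha=d["alpha"], p_inv=d.get("p_inv", 0.0), K=d.get("K", 5))


def transition_matrix(d: float, model: PoissonGI | None = None,
                      category: int | None = None,
                      rate: float | None = None) -> np.ndarray:
    """20×20 transition-probability matrix for branch length ``d``.

    The rate multiplier is either given directly (``rate``) or looked up
    as ``model``'s ``category``-th multiplier; by default the mean rate 1
    is used.  Rows sum to 1 for any ``d >= 0``.
    """
    if d < 0:
        raise ValueError("branch length must be non-negative")
    if category is not None:
        if model is None:
            raise ValueError("category lookup requires a model")
        rate = float(model.rate_multipliers[category])
    elif rate is None:
        rate = 1.0
    e = np.exp(-_POISSON_BETA * d * rate)
    same = 1.0 / N_STATES + (N_STATES - 1) / N_STATES * e
    diff = (1.0 - same) / (N_STATES - 1)
    P = np.full((N_STATES, N_STATES), diff)
    np.fill_diagonal(P, same)
    return P


def poisson_decay(d: np.ndarray | float, rate: float = 1.0) -> np.ndarray | float:
    """exp(-(20/19)·d·rate): the single scalar that determines the whole
    Poisson transition matrix (used by the vectorised likelihood engine)."""
    return np.exp(-_POISSON_BETA * np.asarray(d, dtype=float) * rate)
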