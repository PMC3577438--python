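"""Reversible nucleotide substitution models (JC69, HKY85, GTR) with
discrete-gamma rate heterogeneity.

Rate matrices are normalized to one expected substitution per site per unit
branch length. State order is A, C, G, T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["SubstitutionModel", "JC69", "HKY", "GTR", "discrete_gamma_rates"]


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, 1/alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1, alpha * bounds[1:])
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    return k * (upper - lower)


@dataclass
class SubstitutionModel:
    """Base class: a normalized GTR-family generator with optional +G."""

    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: Optional[float] = None  # gamma shape; None = rate homogeneity
    n_categories: int = 4

    name = "GTR-family"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or abs(self.freqs.sum() - 1) > 1e-8:
            raise ValueError("freqs must be 4 values summing to 1")
        self._decompose()

    # subclasses supply the exchangeability matrix
    def _exchangeabilities(self) -> np.ndarray:
        raise NotImplementedError

    def rate_matrix(self) -> np.ndarray:
        S = self._exchangeabilities()
        Q = S * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.freqs, np.diag(Q)))
        return Q / mu

    def _decompose(self) -> None:
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        Q = self.rate_matrix()
        rt = np.sqrt(self.freqs)
        B = rt[:, None] * Q / rt[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._left = U.T * rt[None, :]       # U^T diag(sqrt pi)
        self._right = (1.0 / rt)[:, None] * U  # diag(1/sqrt pi) U

    def pmatrix(self, t: float) -> np.ndarray:
        """Transition probability matrix for branch length t (subs/site)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = self._right @ (np.exp(self._eigvals * t)[:, None] * self._left)
        return np.clip(P, 0.0, 1.0)

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.array([1.0])
        return discrete_gamma_rates(self.alpha, self.n_categories)

    @property
    def n_free_params(self) -> int:
        """Substitution parameters counted toward AIC. Base frequencies are
        estimated empirically but still count as 3 free parameters (the
        usual model-selection convention) except under JC69."""
        return 3 + (1 if self.alpha is not None else 0)


@dataclass
class JC69(SubstitutionModel):
    name = "JC69"

    def __post_init__(self):
        self.freqs = np.full(4, 0.25)
        super().__post_init__()

    def _exchangeabilities(self) -> np.ndarray:
        S = np.ones((4, 4))
        np.fill_diagonal(S, 0.0)
        return S

    def pmatrix(self, t: float) -> np.ndarray:
        # closed form: faster than the eigen route in inner loops
        if t < 0:
            raise ValueError("branch length must be non-negative")
        e = np.exp(-4.0 * t / 3.0)
        same = 0.25 + 0.75 * e
        diff = 0.25 - 0.25 * e
        P = np.full((4, 4), diff)
        np.fill_diagonal(P, same)
        return P

    @property
    def n_free_params(self) -> int:
        return 1 if self.alpha is not None else 0


@dataclass
class HKY(SubstitutionModel):
    kappa: float = 2.0

    name = "HKY"

    def _exchangeabilities(self) -> np.ndarray:
        S = np.ones((4, 4))
        np.fill_diagonal(S, 0.0)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # transitions
            S[i, j] = self.kappa
        return S

    @property
    def n_free_params(self) -> int:
        return 1 + super().n_free_params


@dataclass
class GTR(SubstitutionModel):
    # exchangeabilities in order AC, AG, AT, CG, CT, GT (GT fixed to 1)
    rates: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )

    name = "GTR"

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (6,):
            raise ValueError("GTR needs 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
        super().__post_init__()

    def _exchangeabilities(self) -> np.ndarray:
        ac, ag, at, cg, ct, gt = self.rates
        S = np.array(
            [
                [0, ac, ag, at],
                [ac, 0, cg, ct],
                [ag, cg, 0, gt],
                [at, ct, gt, 0],
            ],
            dtype=float,
        )
        return S

    @property
    def n_free_params(self) -> int:
        return 5 + super().n_free_params
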