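"""Maximum-likelihood model fitting on a fixed topology and AIC selection.

Candidate models are JC69, HKY, HKY+G, GTR and GTR+G. Branch lengths and
substitution parameters are optimized numerically (L-BFGS-B on log scale);
base frequencies are taken as empirical and not counted as free parameters.
AIC = 2k - 2 lnL with k = free substitution parameters + free branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .likelihood import SitePatterns, compress_patterns, tree_log_likelihood
from .njtree import BLNode
from .substmodels import GTR, HKY, JC69, SubstitutionModel

__all__ = ["ModelFit", "fit_model", "select_model", "aic"]


def aic(k: int, loglik: float) -> float:
    return 2.0 * k - 2.0 * loglik


@dataclass
class ModelFit:
    name: str
    model: SubstitutionModel
    loglik: float
    n_params: int
    aic: float
    converged: bool
    branch_lengths: dict[int, float]  # id(node) -> fitted length


def _empirical_freqs(sequences: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in sequences.values():
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            counts[i] += int((arr == b).sum())
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _make_model(name: str, freqs: np.ndarray, theta: np.ndarray) -> SubstitutionModel:
    if name == "JC69":
        return JC69()
    if name == "HKY":
        return HKY(freqs=freqs, kappa=float(theta[0]))
    if name == "HKY+G":
        return HKY(freqs=freqs, kappa=float(theta[0]), alpha=float(theta[1]))
    if name == "GTR":
        return GTR(freqs=freqs, rates=np.append(theta[:5], 1.0))
    if name == "GTR+G":
        return GTR(freqs=freqs, rates=np.append(theta[:5], 1.0), alpha=float(theta[5]))
    raise KeyError(name)


_THETA0 = {
    "JC69": [],
    "HKY": [2.0],
    "HKY+G": [2.0, 0.5],
    "GTR": [1.0, 2.0, 1.0, 1.0, 2.0],
    "GTR+G": [1.0, 2.0, 1.0, 1.0, 2.0, 0.5],
}


def fit_model(
    sequences: dict[str, str],
    tree: BLNode,
    name: str,
    maxiter: int = 200,
) -> ModelFit:
    """ML-fit one model: joint optimization of branch lengths and parameters."""
    patterns = compress_patterns(sequences)
    freqs = _empirical_freqs(sequences)

    nodes = []
    stack = [tree]
    while stack:
        n = stack.pop()
        if n is not tree:
            nodes.append(n)
        stack.extend(n.children)
    nb = len(nodes)
    theta0 = np.array(_THETA0[name], dtype=float)
    nt = theta0.size
    bl0 = np.array([max(n.length, 1e-4) for n in nodes])
    x0 = np.log(np.concatenate([bl0, np.maximum(theta0, 1e-3)]))

    def unpack(x):
        bl = np.exp(x[:nb])
        theta = np.exp(x[nb:])
        return bl, theta

    def neg_loglik(x):
        bl, theta = unpack(x)
        try:
            model = _make_model(name, freqs, theta)
        except (ValueError, FloatingPointError):
            return 1e12
        lengths = {id(n): float(b) for n, b in zip(nodes, bl)}
        try:
            return -tree_log_likelihood(
                tree, patterns, model, lambda n: lengths[id(n)]
            )
        except FloatingPointError:
            return 1e12

    res = minimize(
        neg_loglik, x0, method="L-BFGS-B",
        bounds=[(np.log(1e-8), np.log(10.0))] * nb
        + [(np.log(1e-3), np.log(100.0))] * nt,
        options={"maxiter": maxiter},
    )
    bl, theta = unpack(res.x)
    model = _make_model(name, freqs, theta)
    # one branch is redundant on a rooted reversible tree: count unrooted edges
    k = (nb - 1) + model.n_free_params
    loglik = -float(res.fun)
    return ModelFit(
        name, model, loglik, k, aic(k, loglik), bool(res.success),
        {id(n): float(b) for n, b in zip(nodes, bl)},
    )


def select_model(
    sequences: dict[str, str],
    tree: BLNode,
    candidates: tuple[str, ...] = ("JC69", "HKY", "HKY+G", "GTR", "GTR+G"),
) -> tuple[ModelFit, list[ModelFit]]:
    """Fit all candidates and return (best by AIC, all fits).

    Non-converged fits are excluded from the choice but kept in the list.
    """
    fits = [fit_model(sequences, tree, name) for name in candidates]
    usable = [f for f in fits if f.converged] or fits
    best = min(usable, key=lambda f: f.aic)
    return best, fits
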