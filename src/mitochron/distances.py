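"""Model-corrected pairwise distances (JC69, TN93, optionally gamma-corrected).

Sites with gaps or ambiguity in either member of a pair are excluded
pairwise. Saturated pairs (a non-positive logarithm argument) are capped at
a maximum distance and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["DistanceMatrix", "jc69_distance", "tn93_distance", "pairwise_distances"]

MAX_DISTANCE = 5.0

_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric, zero-diagonal, non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


def _gamma_log(x: np.ndarray | float, alpha: Optional[float]):
    """-ln(x), or its gamma-rates analogue alpha*(x^(-1/alpha) - 1)."""
    if alpha is None:
        return -np.log(x)
    return alpha * (np.power(x, -1.0 / alpha) - 1.0)


def jc69_distance(seq1: str, seq2: str, alpha: Optional[float] = None) -> tuple[float, bool]:
    """Jukes-Cantor corrected distance; returns (distance, saturated_flag)."""
    a = np.frombuffer(seq1.encode(), dtype=np.uint8)
    b = np.frombuffer(seq2.encode(), dtype=np.uint8)
    valid = np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) & \
        np.isin(b, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = int(valid.sum())
    if n == 0:
        return 0.0, False
    p = float((a[valid] != b[valid]).sum()) / n
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return MAX_DISTANCE, True
    return float(0.75 * _gamma_log(arg, alpha)), False


def tn93_distance(seq1: str, seq2: str, alpha: Optional[float] = None) -> tuple[float, bool]:
    """Tamura-Nei (1993) distance separating the two transition types.

    Base frequencies are the empirical averages over the pair. Returns
    (distance, saturated_flag); collapses to JC-like behaviour on uniform
    data.
    """
    a = np.frombuffer(seq1.encode(), dtype=np.uint8)
    b = np.frombuffer(seq2.encode(), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid = np.isin(a, acgt) & np.isin(b, acgt)
    a, b = a[valid], b[valid]
    n = a.size
    if n == 0:
        return 0.0, False

    idx = np.zeros(256, dtype=int)
    for base, i in _CODE.items():
        idx[ord(base)] = i
    ai, bi = idx[a], idx[b]
    freqs = (np.bincount(ai, minlength=4) + np.bincount(bi, minlength=4)) / (2.0 * n)
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT

    P1 = float(np.sum(((ai == 0) & (bi == 2)) | ((ai == 2) & (bi == 0)))) / n  # A<->G
    P2 = float(np.sum(((ai == 1) & (bi == 3)) | ((ai == 3) & (bi == 1)))) / n  # C<->T
    Q = float(np.sum((ai != bi))) / n - P1 - P2

    if min(gA, gC, gG, gT) <= 0:
        return jc69_distance(seq1, seq2, alpha)

    x1 = 1.0 - gR / (2.0 * gA * gG) * P1 - Q / (2.0 * gR)
    x2 = 1.0 - gY / (2.0 * gC * gT) * P2 - Q / (2.0 * gY)
    x3 = 1.0 - Q / (2.0 * gR * gY)
    if x1 <= 0 or x2 <= 0 or x3 <= 0:
        return MAX_DISTANCE, True
    d = (
        2.0 * gA * gG / gR * _gamma_log(x1, alpha)
        + 2.0 * gC * gT / gY * _gamma_log(x2, alpha)
        + 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        * _gamma_log(x3, alpha)
    )
    return float(max(d, 0.0)), False


def pairwise_distances(
    sm, model: str = "tn93", alpha: Optional[float] = None
) -> DistanceMatrix:
    """Distance matrix over a Supermatrix (or any taxa/sequences carrier)."""
    dist_fn = {"jc69": jc69_distance, "tn93": tn93_distance}[model]
    taxa = list(sm.taxa)
    seqs = list(sm.sequences)
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            d, sat = dist_fn(seqs[i], seqs[j], alpha)
            D[i, j] = D[j, i] = d
            if sat:
                saturated.append((taxa[i], taxa[j]))
    return DistanceMatrix(taxa, D, saturated)
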