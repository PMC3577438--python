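"""Universal long-range tiling primers from a variant-masked consensus.

To amplify any congeneric mitogenome with one primer panel, the known genomes
are aligned, every variable column is masked, and primers are placed only at
conserved sites: a primer footprint may contain at most two masked columns
and none within the last 3 bases of its 3' end. Accepted sites are then tiled
into overlapping long-range amplicons that close the circle — seven products
of 2.0–3.5 kb with >=100 bp overlaps on a ~15.3 kb mosquito mitogenome.

Melting temperatures use the nearest-neighbor model (unified Allawi &
SantaLucia parameters, 50 mM Na+ entropy correction), vectorized over all
windows of the consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genomes import revcomp

__all__ = [
    "MaskedConsensus",
    "PrimerSite",
    "Amplicon",
    "AmpliconScheme",
    "InfeasibleTilingError",
    "build_masked_consensus",
    "scan_primer_sites",
    "design_tiling",
    "nn_melting_temp",
]


# ---------------------------------------------------------------------------
# consensus masking

@dataclass
class MaskedConsensus:
    """Per-column majority base with variant and gap flags."""

    sequence: str
    variant: np.ndarray  # bool per column: >= 2 distinct unambiguous bases
    gap: np.ndarray  # bool per column: any gap observed
    n_sequences: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


def build_masked_consensus(alignment: Sequence[str]) -> MaskedConsensus:
    """Column-wise majority consensus with variant masking.

    ``alignment`` is a list of equal-length aligned genome sequences (gaps as
    ``-``). A column is a variant when two or more distinct unambiguous bases
    occur in it; gap-containing columns are flagged separately (both kinds
    are excluded from primer footprints downstream).
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned sequences")
    ncol = len(alignment[0])
    if any(len(s) != ncol for s in alignment):
        raise ValueError("aligned sequences must have equal length")

    mat = np.array([list(s.upper()) for s in alignment])
    variant = np.zeros(ncol, dtype=bool)
    gap = np.zeros(ncol, dtype=bool)
    cons = []
    for j in range(ncol):
        col = mat[:, j]
        gap[j] = bool(np.any(col == "-"))
        bases, counts = np.unique(col[np.isin(col, list("ACGT"))], return_counts=True)
        variant[j] = len(bases) >= 2
        if len(bases):
            cons.append(bases[np.argmax(counts)])
        else:
            cons.append("N")
    return MaskedConsensus("".join(cons), variant, gap, len(alignment))


# ---------------------------------------------------------------------------
# nearest-neighbor melting temperature

# Allawi & SantaLucia (unified) parameters: dinucleotide -> (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_R = 1.987  # cal/mol/K


def nn_melting_temp(
    seq: str, na_mM: float = 50.0, dnac1_nM: float = 25.0, dnac2_nM: float = 25.0
) -> float:
    """Duplex melting temperature (deg C) by the nearest-neighbor method.

    Unified NN parameters with the 0.368*(N-1)*ln[Na+] entropy salt
    correction and annealing concentration k = dnac1 - dnac2/2 (nM).
    """
    seq = seq.upper()
    dh, ds = 0.0, 0.0
    for a, b in zip(seq, seq[1:]):
        h, s = _NN[a + b]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_AT if terminal in "AT" else _INIT_GC
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    return 1000.0 * dh / (ds + _R * math.log(k)) - 273.15


def _window_tm_gc(seq: str, lengths: range, na_mM: float = 50.0) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Vectorized Tm and GC for every window of every length.

    Returns {length: (tm array over starts, gc array over starts)} where
    start i covers seq[i:i+length]. Windows containing non-ACGT get NaN.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode().upper(), dtype=np.uint8)
    is_acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8))
    is_at = np.isin(arr, np.frombuffer(b"AT", dtype=np.uint8))

    # dinucleotide dH/dS arrays
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    c = code[arr]
    din_h = np.zeros(max(n - 1, 0))
    din_s = np.zeros(max(n - 1, 0))
    lut_h = np.zeros((4, 4))
    lut_s = np.zeros((4, 4))
    for dinuc, (h, s) in _NN.items():
        lut_h[code[ord(dinuc[0])], code[ord(dinuc[1])]] = h
        lut_s[code[ord(dinuc[0])], code[ord(dinuc[1])]] = s
    ok_din = (c[:-1] >= 0) & (c[1:] >= 0)
    din_h[ok_din] = lut_h[c[:-1][ok_din], c[1:][ok_din]]
    din_s[ok_din] = lut_s[c[:-1][ok_din], c[1:][ok_din]]

    cum_h = np.concatenate([[0.0], np.cumsum(din_h)])
    cum_s = np.concatenate([[0.0], np.cumsum(din_s)])
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ok = np.concatenate([[0], np.cumsum(~is_acgt)])

    k_conc = (25.0 - 25.0 / 2.0) * 1e-9
    out = {}
    for L in lengths:
        if L > n:
            continue
        starts = np.arange(n - L + 1)
        dh = cum_h[starts + L - 1] - cum_h[starts]
        ds = cum_s[starts + L - 1] - cum_s[starts]
        for end_idx in (starts, starts + L - 1):
            dh = dh + np.where(is_at[end_idx], _INIT_AT[0], _INIT_GC[0])
            ds = ds + np.where(is_at[end_idx], _INIT_AT[1], _INIT_GC[1])
        ds = ds + 0.368 * (L - 1) * math.log(na_mM / 1000.0)
        tm = 1000.0 * dh / (ds + _R * math.log(k_conc)) - 273.15
        bad = (cum_ok[starts + L] - cum_ok[starts]) > 0
        tm[bad] = np.nan
        gc = (cum_gc[starts + L] - cum_gc[starts]) / L
        out[L] = (tm, gc)
    return out


# ---------------------------------------------------------------------------
# primer sites

@dataclass(frozen=True)
class PrimerSite:
    """Accepted primer placement on the plus-strand coordinate system.

    For ``strand == '-'`` the primer sequence is the reverse complement of
    the window and its 3' end sits at ``start``.
    """

    start: int
    length: int
    strand: str
    tm: float
    gc: float
    variant_count: int
    three_prime_clean: bool
    sequence: str

    def __post_init__(self):
        if self.variant_count > 2 or not self.three_prime_clean:
            raise ValueError("primer site violates conservation constraints")

    @property
    def end(self) -> int:
        return self.start + self.length


def scan_primer_sites(
    consensus: MaskedConsensus,
    tm_range: tuple[float, float] = (45.0, 65.0),
    gc_range: tuple[float, float] = (0.2, 0.6),
    len_range: tuple[int, int] = (18, 27),
    max_variants: int = 2,
    three_prime_clean: int = 3,
    circular: bool = True,
) -> list[PrimerSite]:
    """All windows satisfying the conservation, Tm, GC and length constraints.

    Constraints: at most ``max_variants`` masked columns in the footprint,
    no masked column within the last ``three_prime_clean`` bases of the 3'
    end (checked per strand), no gap column, Tm and GC within range. The
    scan wraps around the circle when ``circular``.
    """
    L0 = len(consensus)
    lmin, lmax = len_range
    ext = lmax - 1 if circular else 0
    seq = consensus.sequence + consensus.sequence[:ext]
    variant = np.concatenate([consensus.variant, consensus.variant[:ext]]).astype(int)
    gap = np.concatenate([consensus.gap, consensus.gap[:ext]]).astype(int)
    cum_var = np.concatenate([[0], np.cumsum(variant)])
    cum_gap = np.concatenate([[0], np.cumsum(gap)])

    tm_gc = _window_tm_gc(seq, range(lmin, lmax + 1))
    sites: list[PrimerSite] = []
    for wlen, (tm, gc) in tm_gc.items():
        n_starts = L0 if circular else len(tm)
        for i in range(min(n_starts, len(tm))):
            t = tm[i]
            if not (tm_range[0] <= t <= tm_range[1]):
                continue
            if not (gc_range[0] <= gc[i] <= gc_range[1]):
                continue
            if cum_gap[i + wlen] - cum_gap[i] > 0:
                continue
            nvar = int(cum_var[i + wlen] - cum_var[i])
            if nvar > max_variants:
                continue
            window = seq[i : i + wlen]
            # plus strand: 3' end is the window's last bases
            if cum_var[i + wlen] - cum_var[i + wlen - three_prime_clean] == 0:
                sites.append(PrimerSite(i, wlen, "+", float(t), float(gc[i]),
                                        nvar, True, window))
            # minus strand: 3' end is the window's first bases
            if cum_var[i + three_prime_clean] - cum_var[i] == 0:
                sites.append(PrimerSite(i, wlen, "-", float(t), float(gc[i]),
                                        nvar, True, revcomp(window)))
    sites.sort(key=lambda s: (s.start, s.strand, s.length))
    return sites


# ---------------------------------------------------------------------------
# tiling design

def _circle_segments(lo: int, hi: int, L: int) -> list[tuple[int, int]]:
    """Intervals on [0, L) covered by the (possibly wrapping) arc [lo, hi]."""
    if hi - lo + 1 >= L:
        return [(0, L - 1)]
    lo %= L
    hi %= L
    if lo <= hi:
        return [(lo, hi)]
    return [(lo, L - 1), (0, hi)]


class InfeasibleTilingError(ValueError):
    """No amplicon scheme satisfies the constraints; carries the blocking
    interval (largest site-free stretch of the circle)."""

    def __init__(self, message: str, blocking_interval: tuple[int, int]):
        super().__init__(message)
        self.blocking_interval = blocking_interval


@dataclass
class Amplicon:
    forward: PrimerSite
    reverse: PrimerSite
    product_length: int


@dataclass
class AmpliconScheme:
    amplicons: list[Amplicon]
    overlaps: list[int]  # overlap with the next amplicon (circular)
    genome_length: int
    circular_closure: bool = True
    warning: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.amplicons)

    def validate(self, min_overlap: int, product_range: tuple[int, int]) -> None:
        """Re-verify every invariant of the emitted scheme."""
        for a in self.amplicons:
            if a.forward.variant_count > 2 or a.reverse.variant_count > 2:
                raise AssertionError("primer with >2 variants in scheme")
            if not (a.forward.three_prime_clean and a.reverse.three_prime_clean):
                raise AssertionError("primer without clean 3' end in scheme")
            if not (product_range[0] <= a.product_length <= product_range[1]):
                raise AssertionError("product length out of range")
        for ov in self.overlaps:
            if ov < min_overlap:
                raise AssertionError("consecutive amplicons under-overlap")
        covered = np.zeros(self.genome_length, dtype=int)
        for a in self.amplicons:
            idx = (a.forward.start + np.arange(a.product_length)) % self.genome_length
            covered[idx] += 1
        if (covered == 0).any():
            raise AssertionError("scheme does not cover the circle")


def _blocking_interval(sites: Sequence[PrimerSite], L: int) -> tuple[int, int]:
    starts = sorted({s.start % L for s in sites}) or [0]
    gaps = []
    for a, b in zip(starts, starts[1:] + [starts[0] + L]):
        gaps.append((b - a, a, b % L))
    g = max(gaps)
    return (g[1], g[2])


def design_tiling(
    sites: Sequence[PrimerSite],
    genome_length: int,
    product_range: tuple[int, int] = (2000, 3500),
    min_overlap: int = 100,
    n_target: int = 7,
    max_branch: int = 25,
) -> AmpliconScheme:
    """Tile the circle with ``n_target`` overlapping amplicons.

    Depth-first search with backtracking over candidate (forward, reverse)
    primer pairings, preferring products near the even-spacing ideal; if no
    scheme with exactly ``n_target`` amplicons exists, the feasible count
    closest to ``n_target`` is returned with a warning.
    """
    if not sites:
        raise ValueError("no primer sites supplied")
    L = genome_length
    if L < product_range[0]:
        raise InfeasibleTilingError(
            f"genome length {L} below minimum product size {product_range[0]}",
            (0, L),
        )
    fwd = sorted([s for s in sites if s.strand == "+"], key=lambda s: s.start % L)
    fwd_starts = np.array([s.start % L for s in fwd])
    rev = [s for s in sites if s.strand == "-"]
    if not fwd or not rev:
        raise InfeasibleTilingError(
            "need primer sites on both strands", _blocking_interval(sites, L)
        )
    rev_by_end = sorted(rev, key=lambda s: s.end % L)
    rev_ends = np.array([s.end % L for s in rev_by_end])

    def rev_candidates(b_mod: int, lo: int, hi: int) -> list[tuple[int, PrimerSite]]:
        """Reverse sites giving product length within [lo, hi] from b_mod."""
        if lo > hi:
            return []
        out = []
        # product end positions fall in [b_mod + lo, b_mod + hi] on the circle
        for seg_lo, seg_hi in _circle_segments(b_mod + lo, b_mod + hi, L):
            i0 = int(np.searchsorted(rev_ends, seg_lo, side="left"))
            i1 = int(np.searchsorted(rev_ends, seg_hi, side="right"))
            for j in range(i0, i1):
                s = rev_by_end[j]
                p = (rev_ends[j] - b_mod) % L
                if p == 0:
                    p = L
                if lo <= p <= hi:
                    out.append((int(p), s))
        return out

    def attempt(n_amp: int) -> Optional[AmpliconScheme]:
        ideal = (L + n_amp * min_overlap) / n_amp
        budget[0] = 50000  # DFS expansion budget per attempt
        step = max(1, len(fwd) // 60)
        for f0 in fwd[::step]:
            s0 = f0.start
            chain = _dfs(f0, s0, s0, 0, n_amp, ideal)
            if chain is not None:
                amps = [Amplicon(f, r, p) for f, r, p in chain]
                # rebuild absolute coordinates to report circular overlaps
                abs_b = [s0]
                abs_e = []
                for i, (f, r, p) in enumerate(chain):
                    abs_e.append(abs_b[i] + p)
                    if i + 1 < n_amp:
                        delta = (chain[i + 1][0].start - abs_b[i]) % L
                        abs_b.append(abs_b[i] + delta)
                overlaps = []
                for i in range(n_amp):
                    nxt_b = abs_b[(i + 1) % n_amp] + (L if i + 1 == n_amp else 0)
                    overlaps.append(abs_e[i] - nxt_b)
                return AmpliconScheme(amps, overlaps, L)
        return None

    budget = [0]

    def _dfs(f: PrimerSite, b_abs: int, s0: int, depth: int, n_amp: int,
             ideal: float) -> Optional[list[tuple[PrimerSite, PrimerSite, int]]]:
        if budget[0] <= 0:
            return None
        budget[0] -= 1
        last = depth == n_amp - 1
        lo, hi = product_range
        if last:
            # closure: product must end in [s0 + L + min_overlap - b, ...]
            need_lo = max(lo, s0 + L + min_overlap - b_abs)
            need_hi = hi
            cands = rev_candidates(b_abs % L, need_lo, need_hi)
            cands.sort(key=lambda c: abs(c[0] - ideal))
            for p, r in cands[:max_branch]:
                return [(f, r, p)]
            return None
        cands = rev_candidates(b_abs % L, lo, hi)
        cands.sort(key=lambda c: abs(c[0] - ideal))
        remaining = n_amp - depth - 1
        for p, r in cands[:max_branch]:
            e_abs = b_abs + p
            if e_abs + remaining * (hi - min_overlap) < s0 + L + min_overlap:
                continue  # cannot reach closure even with maximal products
            # next forward start must fall inside the current product,
            # leaving at least min_overlap of shared sequence
            nxt: list[tuple[int, PrimerSite]] = []
            hi_abs = e_abs - min_overlap
            if hi_abs > b_abs:
                for seg_lo, seg_hi in _circle_segments(b_abs + 1, hi_abs, L):
                    i0 = int(np.searchsorted(fwd_starts, seg_lo, side="left"))
                    i1 = int(np.searchsorted(fwd_starts, seg_hi, side="right"))
                    for j in range(i0, i1):
                        g = fwd[j]
                        delta = (g.start - b_abs) % L
                        if 0 < delta and b_abs + delta <= hi_abs:
                            nxt.append((b_abs + delta, g))
            nxt.sort(key=lambda t: abs(t[0] - (e_abs - min_overlap)))
            for nb_abs, g in nxt[:max_branch]:
                sub = _dfs(g, nb_abs, s0, depth + 1, n_amp, ideal)
                if sub is not None:
                    return [(f, r, p)] + sub
        return None

    scheme = attempt(n_target)
    if scheme is not None:
        scheme.validate(min_overlap, product_range)
        return scheme
    for delta in range(1, n_target):
        for n_amp in (n_target - delta, n_target + delta):
            if n_amp < 1:
                continue
            scheme = attempt(n_amp)
            if scheme is not None:
                scheme.warning = (
                    f"no {n_target}-amplicon scheme; returning {n_amp} amplicons"
                )
                scheme.validate(min_overlap, product_range)
                return scheme
    raise InfeasibleTilingError(
        "no feasible tiling under the given constraints",
        _blocking_interval(sites, L),
    )
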