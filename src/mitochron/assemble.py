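"""Small de Bruijn assembler with coverage cutoff, reference anchoring,
ambiguity-code collapse and majority-vote polishing.

The assembly path mirrors the classic organelle workflow: count k-mers from
the (enriched) read set, drop k-mers below a coverage cutoff (C = 70 on ~500X
shotgun data; cutoff 1 on a deduplicated multiplex read set with k = 31),
emit maximal non-branching paths as contigs, anchor contigs to a reference
mitogenome by exact-match chains, collapse overlaps with IUPAC ambiguity
codes, and polish the draft by replacing any base contradicted by a strict
majority of mapped reads.

k-mers are canonicalized to the lexicographic minimum of the strand pair and
k must be odd so no k-mer is its own reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genomes import revcomp
from .reads import ReadMultiset

__all__ = [
    "KmerGraph",
    "Contig",
    "Layout",
    "Placement",
    "PolishedGenome",
    "build_graph",
    "assemble_contigs",
    "anchor_layout",
    "collapse_layout",
    "polish",
    "rotate_to_match",
    "iupac_code",
    "IUPAC_TO_SET",
]

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_DEC = "ACGT"

SET_TO_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_TO_SET = {v: set(k) for k, v in SET_TO_IUPAC.items()}


def iupac_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of unambiguous bases."""
    expanded: set[str] = set()
    for b in bases:
        expanded |= IUPAC_TO_SET.get(b, {b})
    return SET_TO_IUPAC[frozenset(expanded)]


# ---------------------------------------------------------------------------
# k-mer graph

def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (c & np.uint64(3)))
        c >>= np.uint64(2)
    return rc


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_DEC[code & 3])
        code >>= 2
    return "".join(reversed(out))


@dataclass
class KmerGraph:
    """Canonical k-mer multiset; edges are implicit (k-1)-overlaps."""

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def mask(self) -> int:
        return (1 << (2 * self.k)) - 1

    def canonical(self, code: int) -> int:
        rc = 0
        c = code
        for _ in range(self.k):
            rc = (rc << 2) | (3 - (c & 3))
            c >>= 2
        return min(code, rc)

    def __contains__(self, code: int) -> bool:
        return self.canonical(code) in self.counts

    def coverage(self, code: int) -> int:
        return self.counts.get(self.canonical(code), 0)

    def successors(self, code: int) -> list[int]:
        base = (code << 2) & self.mask
        return [base | b for b in range(4) if (base | b) in self]

    def predecessors(self, code: int) -> list[int]:
        shift = 2 * (self.k - 1)
        base = code >> 2
        return [(b << shift) | base for b in range(4) if ((b << shift) | base) in self]

    def kmer_strings(self) -> set[str]:
        return {_decode(c, self.k) for c in self.counts}

    def __len__(self) -> int:
        return len(self.counts)


def build_graph(sequences: Iterable[str] | ReadMultiset, k: int) -> KmerGraph:
    """Count canonical k-mers from reads or distinct sequences.

    ``k`` must be odd (a k-mer can then never equal its own reverse
    complement) and at least 15.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k < 15:
        raise ValueError("k must be >= 15")
    if isinstance(sequences, ReadMultiset):
        sequences = [s for s, _ in sequences.mates()]
    # batch equal-length sequences into one matrix for vectorized extraction
    by_len: dict[int, list[str]] = {}
    for seq in sequences:
        if len(seq) >= k:
            by_len.setdefault(len(seq), []).append(seq)
    all_codes = []
    for length, group in by_len.items():
        mat = _ENC[
            np.frombuffer("".join(group).encode(), dtype=np.uint8)
        ].reshape(len(group), length)
        n_win = length - k + 1
        codes = np.zeros((len(group), n_win), dtype=np.uint64)
        ok = np.ones((len(group), n_win), dtype=bool)
        for off in range(k):
            col = mat[:, off : off + n_win]
            ok &= col != 255
            codes = (codes << np.uint64(2)) | col.astype(np.uint64)
        codes = codes[ok]
        rc = _rc_codes(codes, k)
        all_codes.append(np.minimum(codes, rc))
    graph = KmerGraph(k=k)
    if all_codes:
        cat = np.concatenate(all_codes)
        uniq, cnt = np.unique(cat, return_counts=True)
        graph.counts = dict(zip(uniq.tolist(), cnt.tolist()))
    return graph


# ---------------------------------------------------------------------------
# contigs

@dataclass
class Contig:
    sequence: str
    mean_coverage: float
    id: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def assemble_contigs(graph: KmerGraph, min_kmer_coverage: int = 70) -> list[Contig]:
    """Maximal non-branching paths after removing low-coverage k-mers.

    ``min_kmer_coverage`` plays the role of the assembler's coverage cutoff
    (70 on raw ~500X shotgun counts; use 1 on deduplicated input).
    """
    k = graph.k
    kept = KmerGraph(
        k=k,
        counts={c: n for c, n in graph.counts.items() if n >= min_kmer_coverage},
    )
    if not kept.counts:
        return []

    used: set[int] = set()
    contigs: list[Contig] = []

    def unique_next(code: int) -> Optional[int]:
        succ = kept.successors(code)
        if len(succ) != 1:
            return None
        nxt = succ[0]
        if len(kept.predecessors(nxt)) != 1:
            return None
        return nxt

    def unique_prev(code: int) -> Optional[int]:
        pred = kept.predecessors(code)
        if len(pred) != 1:
            return None
        prv = pred[0]
        if len(kept.successors(prv)) != 1:
            return None
        return prv

    for start_canon in sorted(kept.counts):
        if start_canon in used:
            continue
        # walk right then left from the canonical orientation
        path = [start_canon]
        seen = {start_canon}
        circular = False
        node = start_canon
        while True:
            nxt = unique_next(node)
            if nxt is None:
                break
            canon = kept.canonical(nxt)
            if canon == start_canon and len(path) > 1:
                circular = True
                break
            if canon in used or canon in seen:
                break
            path.append(nxt)
            seen.add(canon)
            node = nxt
        if not circular:
            node = start_canon
            left: list[int] = []
            while True:
                prv = unique_prev(node)
                if prv is None:
                    break
                canon = kept.canonical(prv)
                if canon in used or canon in seen:
                    break
                left.append(prv)
                seen.add(canon)
                node = prv
            path = list(reversed(left)) + path

        seq = _decode(path[0], k) + "".join(_DEC[p & 3] for p in path[1:])
        covs = [kept.counts[kept.canonical(p)] for p in path]
        for p in path:
            used.add(kept.canonical(p))
        contigs.append(
            Contig(seq, float(np.mean(covs)), f"contig{len(contigs) + 1}", circular)
        )
    contigs.sort(key=len, reverse=True)
    for i, c in enumerate(contigs):
        c.id = f"contig{i + 1}"
    return contigs


# ---------------------------------------------------------------------------
# reference anchoring

@dataclass
class Placement:
    contig: Contig
    start: int  # 0-based on the reference (may exceed length-1 via wrap: end > L)
    end: int
    strand: str

    @property
    def oriented_sequence(self) -> str:
        return self.contig.sequence if self.strand == "+" else revcomp(self.contig.sequence)


@dataclass
class Layout:
    placements: list[Placement]
    reference_length: int
    unplaced: list[Contig] = field(default_factory=list)

    def overlaps(self) -> list[int]:
        """Overlap length between consecutive placements (reference order)."""
        out = []
        for a, b in zip(self.placements, self.placements[1:]):
            out.append(max(0, a.end - b.start))
        return out


def anchor_layout(
    contigs: Sequence[Contig], reference, anchor_min: int = 20
) -> Layout:
    """Place each contig on the reference by its best exact-match diagonal.

    Seeds of length ``anchor_min`` from the contig are looked up in a doubled
    (circular) reference index on both strands; the (strand, diagonal) with
    the most seed support wins. Contigs with no seed hit are reported
    unplaced.
    """
    ref_seq = reference.sequence if hasattr(reference, "sequence") else str(reference)
    L = len(ref_seq)
    doubled = ref_seq + ref_seq
    index: dict[str, list[int]] = {}
    for i in range(len(doubled) - anchor_min + 1):
        index.setdefault(doubled[i : i + anchor_min], []).append(i)

    placements: list[Placement] = []
    unplaced: list[Contig] = []
    for contig in contigs:
        best = None  # (votes, strand, diagonal)
        for strand, seq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
            votes: dict[int, int] = {}
            step = max(1, anchor_min // 2)
            for cpos in range(0, len(seq) - anchor_min + 1, step):
                for rpos in index.get(seq[cpos : cpos + anchor_min], []):
                    if rpos >= L and rpos - cpos >= L:
                        continue  # duplicate image of the same diagonal
                    diag = (rpos - cpos) % L
                    votes[diag] = votes.get(diag, 0) + 1
            for diag, v in votes.items():
                if best is None or v > best[0]:
                    best = (v, strand, diag)
        if best is None:
            unplaced.append(contig)
            continue
        _, strand, diag = best
        placements.append(Placement(contig, diag, diag + len(contig), strand))
    placements.sort(key=lambda p: (p.start, p.end))
    return Layout(placements, L, unplaced)


# ---------------------------------------------------------------------------
# collapse

def collapse_layout(layout: Layout) -> tuple[str, list[tuple[int, int]]]:
    """Collapse placed contigs into a draft consensus on reference coordinates.

    Positions where placed contigs agree pass through; disagreements become
    the minimal IUPAC code covering the observed bases; uncovered reference
    positions are emitted as N and returned as gap intervals (0-based
    half-open) in the gap report.
    """
    L = layout.reference_length
    observed: list[set[str]] = [set() for _ in range(L)]
    for p in layout.placements:
        seq = p.oriented_sequence
        for off, base in enumerate(seq):
            observed[(p.start + off) % L].add(base)

    out = []
    gaps: list[tuple[int, int]] = []
    gap_start = None
    for i in range(L):
        if not observed[i]:
            out.append("N")
            if gap_start is None:
                gap_start = i
            continue
        if gap_start is not None:
            gaps.append((gap_start, i))
            gap_start = None
        out.append(iupac_code(observed[i]))
    if gap_start is not None:
        gaps.append((gap_start, L))
    return "".join(out), gaps


# ---------------------------------------------------------------------------
# polishing

@dataclass
class PolishedGenome:
    sequence: str
    depth: np.ndarray
    corrected: np.ndarray  # bool per position
    uncovered: np.ndarray  # bool per position (left unchanged, flagged)

    @property
    def n_corrections(self) -> int:
        return int(self.corrected.sum())


def polish(
    draft: str,
    reads: ReadMultiset,
    k_map: int = 31,
    circular: bool = True,
) -> PolishedGenome:
    """Majority-vote polishing by exact-seed read mapping.

    Each mate is seeded by its first ``k_map``-mer (both strands) against the
    draft and extended ungapped; per-position base counts are tallied from
    all mapped reads. A draft base is replaced only where some alternative
    base is carried by a strict majority (> 50%) of covering reads; ambiguous
    (IUPAC) draft positions are resolved to the plurality base. Zero-coverage
    positions are left unchanged and flagged.
    """
    L = len(draft)
    ref = draft + draft[: k_map + reads.read_length] if circular else draft
    index: dict[str, int] = {}
    for i in range(min(len(ref), L) ):
        kmer = ref[i : i + k_map]
        if len(kmer) == k_map and kmer not in index:
            index[kmer] = i

    counts = np.zeros((L, 4), dtype=np.int64)
    for seq, _ in reads.mates():
        for oriented in (seq, revcomp(seq)):
            pos = index.get(oriented[:k_map])
            if pos is None:
                continue
            if not circular and pos + len(oriented) > L:
                continue
            arr = _ENC[np.frombuffer(oriented.encode(), dtype=np.uint8)]
            valid = arr != 255
            idx = (pos + np.arange(arr.size)) % L
            np.add.at(counts, (idx[valid], arr[valid]), 1)
            break

    depth = counts.sum(axis=1)
    corrected = np.zeros(L, dtype=bool)
    uncovered = depth == 0
    out = list(draft)
    for i in range(L):
        if depth[i] == 0:
            continue
        top = int(np.argmax(counts[i]))
        top_base = _DEC[top]
        if counts[i, top] * 2 > depth[i] and top_base != draft[i]:
            # strict majority contradicting the draft (covers IUPAC resolution)
            out[i] = top_base
            corrected[i] = True
    return PolishedGenome("".join(out), depth, corrected, uncovered)


def rotate_to_match(sequence: str, reference: str) -> Optional[str]:
    """Rotate a circular sequence (or its reverse complement) to start where
    the reference starts; None when no rotation matches exactly."""
    if len(sequence) != len(reference):
        return None
    for cand in (sequence, revcomp(sequence)):
        doubled = cand + cand
        idx = doubled.find(reference)
        if idx != -1:
            return doubled[idx : idx + len(reference)]
    return None
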