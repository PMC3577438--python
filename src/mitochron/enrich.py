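"""Read-selection heuristics that enrich for mitochondrial reads.

At ~500X mitochondrial versus single-digit nuclear coverage, identical reads
recur only when they come from the high-copy molecule, so exact-duplicate
reads are almost certainly mitochondrial. Two count-based filters exploit
this: keep reads whose sequence occurs at least twice (shotgun enrichment),
or keep one instance of each sequence seen in strictly more than 20 reads
(multiplex abundance filter with deduplication). Quality values are ignored;
reverse complements are not collapsed unless requested.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .genomes import revcomp
from .reads import ReadMultiset

__all__ = [
    "EnrichmentReport",
    "select_duplicated_reads",
    "abundance_filter_dedup",
    "estimate_copy_ratio",
]


@dataclass
class EnrichmentReport:
    """Counts and (when truth labels exist) purity/recall of a filtering step."""

    input_reads: int
    retained_reads: int
    distinct_retained: int
    purity: Optional[float] = None  # fraction of retained mates truly mt
    recall: Optional[float] = None  # fraction of mt mates retained

    def __post_init__(self):
        if self.retained_reads > self.input_reads:
            raise ValueError("retained cannot exceed input")
        for v in (self.purity, self.recall):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("purity/recall must lie in [0, 1]")


def _counts(reads: ReadMultiset, collapse_rc: bool) -> Counter:
    c: Counter = Counter()
    for seq, _ in reads.mates():
        c[min(seq, revcomp(seq)) if collapse_rc else seq] += 1
    return c


def _key(seq: str, collapse_rc: bool) -> str:
    return min(seq, revcomp(seq)) if collapse_rc else seq


def select_duplicated_reads(
    reads: ReadMultiset,
    min_multiplicity: int = 2,
    require_pair_concordance: bool = False,
    collapse_rc: bool = False,
) -> tuple[ReadMultiset, EnrichmentReport]:
    """Keep every read copy whose exact sequence occurs ``min_multiplicity``+ times.

    Each mate is filtered independently by default; with
    ``require_pair_concordance`` a pair is kept only when both mates pass.
    Returns the filtered multiset (multiplicities preserved — all copies of a
    passing sequence are retained) and a report.
    """
    if min_multiplicity < 1:
        raise ValueError("min_multiplicity must be >= 1")
    if len(reads) == 0:
        raise ValueError("empty read set")

    counts = _counts(reads, collapse_rc)
    keep_idx = []
    kept_mt = kept_total = 0
    for i, p in enumerate(reads.pairs):
        ok1 = counts[_key(p.r1, collapse_rc)] >= min_multiplicity
        ok2 = counts[_key(p.r2, collapse_rc)] >= min_multiplicity
        keep = (ok1 and ok2) if require_pair_concordance else (ok1 or ok2)
        if keep:
            keep_idx.append(i)
            kept_total += 2
            if p.origin == "mt":
                kept_mt += 2

    filtered = reads.subset(keep_idx)
    have_truth = all(p.origin is not None for p in reads.pairs) and len(reads) > 0
    purity = recall = None
    if have_truth:
        total_mt = 2 * sum(1 for p in reads.pairs if p.origin == "mt")
        purity = kept_mt / kept_total if kept_total else 0.0
        recall = kept_mt / total_mt if total_mt else 0.0
    report = EnrichmentReport(
        input_reads=reads.n_mates,
        retained_reads=filtered.n_mates,
        distinct_retained=len({s for s, _ in filtered.mates()}),
        purity=purity,
        recall=recall,
    )
    return filtered, report


def abundance_filter_dedup(
    reads: ReadMultiset, min_count: int = 20, collapse_rc: bool = False
) -> list[str]:
    """One instance of each distinct sequence represented by > ``min_count`` reads.

    The inequality is strict: a sequence seen exactly ``min_count`` times is
    excluded. Output order is deterministic (sorted).
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = _counts(reads, collapse_rc)
    return sorted(s for s, n in counts.items() if n > min_count)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def estimate_copy_ratio(
    reads: ReadMultiset,
    mt_marker_seqs: Sequence[str],
    nuclear_marker_seq: str,
    k: int = 31,
) -> tuple[float, bool]:
    """Coverage-ratio diagnostic: per-bp mt-marker coverage over nuclear-marker.

    Reads are assigned to a marker when they share an exact k-mer with it
    (either strand). Mirrors the mapping-based check that mitochondrial genes
    (COI, CO2) run ~50–60-fold deeper than a single-copy nuclear gene (VGSC).

    Returns (ratio, warning): warning is True when nuclear coverage is zero,
    in which case the ratio is ``inf`` (or 0.0 when nothing matches at all).
    """
    for m in list(mt_marker_seqs) + [nuclear_marker_seq]:
        if len(m) < 200:
            raise ValueError("markers must be >= 200 bp")
    if k > reads.read_length:
        raise ValueError("k exceeds read length")

    mt_index: set[str] = set()
    for m in mt_marker_seqs:
        mt_index |= _kmers(m, k) | _kmers(revcomp(m), k)
    nuc_index = _kmers(nuclear_marker_seq, k) | _kmers(revcomp(nuclear_marker_seq), k)

    mt_bases = nuc_bases = 0
    for seq, _ in reads.mates():
        hit_mt = any(seq[i : i + k] in mt_index for i in range(0, len(seq) - k + 1, k))
        hit_nuc = any(seq[i : i + k] in nuc_index for i in range(0, len(seq) - k + 1, k))
        if not (hit_mt or hit_nuc):
            # strided probe missed: fall back to full scan once
            hit_mt = any(s in mt_index for s in _kmers(seq, k))
            hit_nuc = not hit_mt and any(s in nuc_index for s in _kmers(seq, k))
        if hit_mt:
            mt_bases += len(seq)
        elif hit_nuc:
            nuc_bases += len(seq)

    mt_len = sum(len(m) for m in mt_marker_seqs)
    mt_cov = mt_bases / mt_len
    nuc_cov = nuc_bases / len(nuclear_marker_seq)
    if nuc_cov == 0:
        return (0.0, False) if mt_cov == 0 else (float("inf"), True)
    return mt_cov / nuc_cov, False
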