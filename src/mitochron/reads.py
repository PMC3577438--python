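"""Paired-end shotgun read simulation and the read multiset container.

Reads are drawn uniformly from circular mitochondrial genomes and a linear
nuclear background in proportion to the mitochondrial copy ratio, emulating
whole-genome shotgun data in which organelle reads are heavily over-represented
(mosquito data show a ~50–60-fold mt:nuclear coverage excess, ~500X mt).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

import numpy as np

from .genomes import Mitogenome, revcomp

__all__ = ["ReadPair", "ReadMultiset", "shotgun_reads", "write_fastq_pair", "read_fastq"]

_Q30 = "I"  # constant phred-30 quality


@dataclass(frozen=True)
class ReadPair:
    """One sequenced fragment: forward mate, reverse mate, insert size."""

    r1: str
    r2: str
    insert: int
    origin: Optional[str] = None  # 'mt' | 'nuclear' | None when unknown


@dataclass
class ReadMultiset:
    """A collection of paired-end reads with multiplicity bookkeeping.

    Multiplicity is counted on exact full-length mate sequences (each mate
    independently); origins are per-pair labels available in simulation.
    """

    pairs: list[ReadPair] = field(default_factory=list)
    read_length: int = 0

    def __post_init__(self):
        if self.pairs and self.read_length == 0:
            self.read_length = len(self.pairs[0].r1)
        for p in self.pairs:
            if len(p.r1) != self.read_length or len(p.r2) != self.read_length:
                raise ValueError("read length must be constant within a set")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_mates(self) -> int:
        return 2 * len(self.pairs)

    def mates(self) -> Iterable[tuple[str, str | None]]:
        """Yield (sequence, origin) for every mate."""
        for p in self.pairs:
            yield p.r1, p.origin
            yield p.r2, p.origin

    def mate_counts(self) -> Counter:
        """Multiplicity of every distinct mate sequence."""
        c: Counter = Counter()
        for seq, _ in self.mates():
            c[seq] += 1
        return c

    def subset(self, keep: list[int]) -> "ReadMultiset":
        return ReadMultiset([self.pairs[i] for i in keep], self.read_length)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _draw_pairs(
    source: str,
    circular: bool,
    n_pairs: int,
    read_len: int,
    insert_mean: int,
    insert_sd: float,
    error_rate: float,
    origin: str,
    rng: np.random.Generator,
) -> list[ReadPair]:
    L = len(source)
    doubled = source + source if circular else source
    out = []
    for _ in range(n_pairs):
        insert = max(2 * read_len, int(round(rng.normal(insert_mean, insert_sd))))
        if circular:
            start = int(rng.integers(L))
        else:
            insert = min(insert, L)
            start = int(rng.integers(L - insert + 1))
        frag = doubled[start : start + insert]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        out.append(
            ReadPair(
                _apply_errors(r1, error_rate, rng),
                _apply_errors(r2, error_rate, rng),
                insert,
                origin,
            )
        )
    return out


def shotgun_reads(
    genomes: dict[str, Mitogenome] | list[Mitogenome],
    nuclear_background: str,
    copy_ratio: float = 55.0,
    mean_coverage: float = 500.0,
    read_len: int = 100,
    insert_mean: int = 300,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    seed: Optional[int] = None,
) -> dict[str, ReadMultiset]:
    """Simulate one paired-end shotgun set per mitogenome.

    ``mean_coverage`` is the per-bp mt coverage target; the nuclear background
    is sampled at ``mean_coverage / copy_ratio``, so per-copy sampling depths
    realize the requested mt:nuclear copy ratio. Fragments average
    ``insert_mean`` bp (default 300); both mates are ``read_len`` bp.

    Returns a dict taxon -> ReadMultiset (with per-read origin labels).
    """
    if copy_ratio < 1:
        raise ValueError("copy_ratio must be >= 1")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if isinstance(genomes, list):
        genomes = {g.taxon or f"genome{i}": g for i, g in enumerate(genomes)}

    rng = np.random.default_rng(seed)
    out: dict[str, ReadMultiset] = {}
    for taxon, genome in genomes.items():
        L = len(genome.sequence)
        if read_len > L or (nuclear_background and read_len > len(nuclear_background)):
            raise ValueError("read_len exceeds source sequence length")
        n_mt = int(round(mean_coverage * L / (2 * read_len)))
        pairs = _draw_pairs(
            genome.sequence, True, n_mt, read_len, insert_mean, insert_sd,
            error_rate, "mt", rng,
        )
        if nuclear_background:
            cov_nuc = mean_coverage / copy_ratio
            n_nuc = int(round(cov_nuc * len(nuclear_background) / (2 * read_len)))
            pairs += _draw_pairs(
                nuclear_background, False, n_nuc, read_len, insert_mean,
                insert_sd, error_rate, "nuclear", rng,
            )
        out[taxon] = ReadMultiset(pairs, read_len)
    return out


# ---------------------------------------------------------------------------
# FASTQ I/O

def write_fastq_pair(reads: ReadMultiset, handle1: TextIO, handle2: TextIO,
                     prefix: str = "read") -> None:
    """Write the pair as two FASTQ files with /1 and /2 suffixes, constant Q30."""
    q = _Q30
    for i, p in enumerate(reads.pairs):
        handle1.write(f"@{prefix}{i}/1\n{p.r1}\n+\n{q * len(p.r1)}\n")
        handle2.write(f"@{prefix}{i}/2\n{p.r2}\n+\n{q * len(p.r2)}\n")


def read_fastq(handle: TextIO) -> list[tuple[str, str]]:
    """Minimal FASTQ reader: list of (id, sequence)."""
    out = []
    lines = [l.rstrip("\n") for l in handle]
    for i in range(0, len(lines) - 3, 4):
        if not lines[i].startswith("@"):
            raise ValueError(f"malformed FASTQ at line {i + 1}")
        out.append((lines[i][1:], lines[i + 1]))
    return out


def pair_from_fastq(handle1: TextIO, handle2: TextIO) -> ReadMultiset:
    """Build a ReadMultiset from two mate FASTQ files."""
    r1 = read_fastq(handle1)
    r2 = read_fastq(handle2)
    if len(r1) != len(r2):
        raise ValueError("mate files differ in read count")
    pairs = [ReadPair(a[1], b[1], 0) for a, b in zip(r1, r2)]
    return ReadMultiset(pairs)
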