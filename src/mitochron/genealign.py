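"""Translated gene extraction, codon-aware alignment and supermatrix assembly.

The 13 mitochondrial protein-coding genes are located by local protein
alignment of reference amino-acid sequences (classically the *Drosophila
melanogaster* annotations) against all six reading frames of each genome
under the invertebrate mitochondrial genetic code (NCBI translation table 5:
TGA=Trp, ATA=Met, AGA/AGG=Ser). Per-gene nucleotide sequences are aligned at
the amino-acid level and back-translated so that gaps always occur in
frame-preserving triplets, then concatenated into a partitioned supermatrix
(gene intervals, codon-position classes 1+2 versus 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio import SeqIO

from .genomes import Mitogenome, PCG_NAMES, revcomp

__all__ = [
    "ProteinReference",
    "GeneHit",
    "CodonAlignment",
    "Supermatrix",
    "translate_mt",
    "extract_genes",
    "codon_align",
    "concatenate",
]

TRANSLATION_TABLE = 5  # invertebrate mitochondrial code

# common GenBank gene-name synonyms -> canonical names
_SYNONYMS = {
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6", "COI": "COX1",
    "CO1": "COX1", "COII": "COX2", "CO2": "COX2", "COIII": "COX3",
    "CO3": "COX3", "COB": "CYTB", "CYTB": "CYTB", "ATP6": "ATP6",
    "ATP8": "ATP8", "ATPASE6": "ATP6", "ATPASE8": "ATP8",
}


def translate_mt(cds: str) -> str:
    """Translate a coding sequence under the invertebrate mt code."""
    return str(Seq(cds).translate(table=TRANSLATION_TABLE))


@dataclass
class ProteinReference:
    """The 13 reference mitochondrial protein sequences used for search."""

    proteins: dict[str, str]

    def __post_init__(self):
        missing = set(PCG_NAMES) - set(self.proteins)
        if missing:
            raise ValueError(f"missing reference proteins: {sorted(missing)}")
        if len(self.proteins) != 13:
            extra = set(self.proteins) - set(PCG_NAMES)
            raise ValueError(f"unexpected reference entries: {sorted(extra)}")

    @classmethod
    def from_genome(cls, genome: Mitogenome) -> "ProteinReference":
        """Translate the annotated CDS of a template-carrying genome."""
        prots = {}
        for name in PCG_NAMES:
            aa = translate_mt(genome.cds(name))
            prots[name] = aa.rstrip("*")
        return cls(prots)

    @classmethod
    def from_genbank(cls, path: str) -> "ProteinReference":
        """Read the 13 protein translations from a GenBank record
        (e.g. a downloaded *D. melanogaster* mitogenome)."""
        record = next(SeqIO.parse(path, "genbank"))
        prots: dict[str, str] = {}
        for feat in record.features:
            if feat.type != "CDS":
                continue
            name = (feat.qualifiers.get("gene") or feat.qualifiers.get("product") or [""])[0]
            canon = _SYNONYMS.get(name.upper().replace("-", ""), name.upper())
            if canon in PCG_NAMES:
                tr = feat.qualifiers.get("translation")
                if tr:
                    prots[canon] = tr[0]
                else:
                    prots[canon] = translate_mt(str(feat.extract(record.seq))).rstrip("*")
        return cls(prots)


@dataclass
class GeneHit:
    """Best placement of one protein-coding gene on a genome."""

    gene: str
    start: int  # 0-based on the plus strand; end may exceed genome length (wrap)
    end: int
    strand: str
    frame: int
    score: float
    percent_identity: float
    cds: str  # coding-strand nucleotide sequence

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("extracted CDS length not divisible by 3")


def _protein_aligner(local: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local" if local else "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _clean_aa(aa: str) -> str:
    """Replace symbols absent from BLOSUM62 (from IUPAC-ambiguous codons)."""
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in allowed else "X" for c in aa)


def extract_genes(
    genome: Mitogenome,
    refs: ProteinReference,
    min_score_fraction: float = 0.3,
) -> tuple[list[GeneHit], list[str]]:
    """Locate each reference protein by six-frame translated local alignment.

    The genome is treated as circular (genes may span the origin). Returns
    (hits, missing): one best-scoring hit per gene, plus the names of genes
    whose best score fell below ``min_score_fraction`` of the reference
    self-alignment score.
    """
    if len(genome.sequence) < 10_000:
        raise ValueError("genome shorter than 10 kb")
    L = len(genome.sequence)
    doubled = genome.sequence + genome.sequence
    aligner = _protein_aligner(local=True)

    frames = []  # (strand, offset, aa string)
    for off in range(3):
        n = (len(doubled) - off) // 3 * 3
        frames.append(("+", off, _clean_aa(translate_mt(doubled[off : off + n]))))
    rc = revcomp(doubled)
    for off in range(3):
        n = (len(rc) - off) // 3 * 3
        frames.append(("-", off, _clean_aa(translate_mt(rc[off : off + n]))))

    hits: list[GeneHit] = []
    missing: list[str] = []
    for gene in PCG_NAMES:
        ref_aa = _clean_aa(refs.proteins[gene])
        self_score = aligner.score(ref_aa, ref_aa)
        best = None  # (score, strand, off, t0, t1)
        for strand, off, aa in frames:
            alns = aligner.align(aa, ref_aa)
            if len(alns) == 0:
                continue
            aln = alns[0]
            t0, t1 = aln.aligned[0][0][0], aln.aligned[0][-1][1]
            if best is None or aln.score > best[0]:
                best = (aln.score, strand, off, t0, t1, aln)
        if best is None or best[0] < min_score_fraction * self_score:
            missing.append(gene)
            continue
        score, strand, off, t0, t1, aln = best
        a = off + 3 * t0  # on the searched strand's doubled sequence
        b = off + 3 * t1
        if strand == "+":
            start, end = a, b
        else:
            start, end = 2 * L - b, 2 * L - a
        # map into [0, L)
        if start >= L:
            start -= L
            end -= L
        # include the terminal stop codon when present (references carry
        # only the protein span)
        if strand == "+":
            nxt = genome.fetch(end, end + 3)
            if nxt in ("TAA", "TAG"):
                end += 3
        else:
            nxt = revcomp(genome.fetch((start - 3) % L, (start - 3) % L + 3))
            if nxt in ("TAA", "TAG"):
                start -= 3
                if start < 0:
                    start += L
                    end += L
        cds = genome.fetch(start, end)
        if strand == "-":
            cds = revcomp(cds)
        ident = _percent_identity(aln)
        hits.append(GeneHit(gene, start, end, strand, off % 3, float(score), ident, cds))
    return hits, missing


def _percent_identity(aln) -> float:
    t, q = str(aln[0]), str(aln[1])
    pairs = [(a, b) for a, b in zip(t, q) if a != "-" and b != "-"]
    if not pairs:
        return 0.0
    return 100.0 * sum(a == b for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# codon-aware alignment

@dataclass
class CodonAlignment:
    """Frame-preserving nucleotide alignment of one gene across taxa."""

    gene: str
    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError("aligned sequences differ in length")
        if self.length % 3 != 0:
            raise ValueError("aligned length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def ungapped(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)].replace("-", "")


class InternalStopError(ValueError):
    def __init__(self, taxon: str, position: int):
        super().__init__(
            f"internal stop codon in {taxon} at codon {position}"
        )
        self.taxon = taxon
        self.position = position


def _aa_kmer_similarity(a: str, b: str, k: int = 3) -> float:
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / min(len(sa), len(sb))


def codon_align(cds_per_taxon: dict[str, str], gene: str = "") -> CodonAlignment:
    """Translate–align–back-translate one gene across taxa.

    Proteins are aligned by a center-star strategy (the most similar-to-all
    sequence anchors pairwise global alignments, merged on its coordinates),
    and gaps are back-translated as whole codons, so the alignment length is
    always a multiple of 3 and ungapping any row recovers its input CDS.
    """
    taxa = list(cds_per_taxon)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    aas: dict[str, str] = {}
    for taxon, cds in cds_per_taxon.items():
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length of {taxon} not divisible by 3")
        aa = translate_mt(cds)
        internal = aa[:-1].find("*")
        if internal != -1:
            raise InternalStopError(taxon, internal)
        aas[taxon] = _clean_aa(aa)

    # center = sequence with greatest summed k-mer similarity to the others
    totals = {
        t: sum(_aa_kmer_similarity(aas[t], aas[u]) for u in taxa if u != t)
        for t in taxa
    }
    center = max(taxa, key=lambda t: (totals[t], -taxa.index(t)))
    others = sorted(
        [t for t in taxa if t != center],
        key=lambda t: -_aa_kmer_similarity(aas[center], aas[t]),
    )

    aligner = _protein_aligner(local=False)
    m = len(aas[center])
    ins = [0] * (m + 1)  # max insertion length before center residue j
    rows: dict[str, tuple[list[str], list[str]]] = {}
    for t in others:
        aln = aligner.align(aas[center], aas[t])[0]
        cg, tg = str(aln[0]), str(aln[1])
        inserts: list[str] = [""] * (m + 1)
        matches: list[str] = []
        j = 0
        for a, b in zip(cg, tg):
            if a == "-":
                inserts[j] += b
            else:
                matches.append(b)
                j += 1
        rows[t] = (inserts, matches)
        for j in range(m + 1):
            ins[j] = max(ins[j], len(inserts[j]))

    def build_row(inserts: list[str], matches: list[str]) -> str:
        out = []
        for j in range(m + 1):
            pad = inserts[j] + "-" * (ins[j] - len(inserts[j]))
            out.append(pad)
            if j < m:
                out.append(matches[j])
        return "".join(out)

    aa_rows = {center: build_row([""] * (m + 1), list(aas[center]))}
    for t in others:
        aa_rows[t] = build_row(*rows[t])

    nt_rows: list[str] = []
    for t in taxa:
        cds = cds_per_taxon[t]
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        it = iter(codons)
        nt_rows.append("".join("---" if c == "-" else next(it) for c in aa_rows[t]))
    return CodonAlignment(gene, taxa, nt_rows)


# ---------------------------------------------------------------------------
# supermatrix

@dataclass
class Supermatrix:
    """Concatenated codon alignments with gene and codon-position partitions."""

    taxa: list[str]
    sequences: list[str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 0-based half-open
    codon_class: np.ndarray = field(default=None)  # 0 for positions 1+2, 1 for 3
    gap_filled: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("unequal sequence lengths")
        if self.codon_class is None:
            cc = np.zeros(self.length, dtype=int)
            for _, start, end in self.partitions:
                cc[start + 2 : end : 3] = 1
            self.codon_class = cc

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def class_columns(self, cls: int) -> np.ndarray:
        return np.nonzero(self.codon_class == cls)[0]

    # -- output ------------------------------------------------------------

    def write_phylip(self, handle) -> None:
        handle.write(f" {len(self.taxa)} {self.length}\n")
        for t, s in zip(self.taxa, self.sequences):
            handle.write(f"{t}  {s}\n")

    def write_nexus(self, handle) -> None:
        handle.write("#NEXUS\nBEGIN DATA;\n")
        handle.write(f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.length};\n")
        handle.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t, s in zip(self.taxa, self.sequences):
            handle.write(f"    {t}  {s}\n")
        handle.write("  ;\nEND;\nBEGIN SETS;\n")
        for gene, start, end in self.partitions:
            handle.write(f"  CHARSET {gene} = {start + 1}-{end};\n")
        handle.write("END;\n")

    def write_partition_tsv(self, handle) -> None:
        handle.write("gene\tstart\tend\tcodon_class\n")
        for gene, start, end in self.partitions:
            handle.write(f"{gene}\t{start}\t{end}\t1+2,3\n")


def concatenate(
    alignments: Sequence[CodonAlignment], taxa: Optional[Sequence[str]] = None
) -> Supermatrix:
    """Concatenate per-gene codon alignments into one partitioned matrix.

    Taxa missing from a gene are filled with gaps and recorded in
    ``gap_filled``. Column classes tile 1,2,3 within each gene's frame.
    """
    if taxa is None:
        seen: list[str] = []
        for aln in alignments:
            for t in aln.taxa:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")

    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    gap_filled: list[tuple[str, str]] = []
    pos = 0
    for aln in alignments:
        for t in taxa:
            if t in aln.taxa:
                chunks[t].append(aln.sequences[aln.taxa.index(t)])
            else:
                chunks[t].append("-" * aln.length)
                gap_filled.append((t, aln.gene))
        parts.append((aln.gene, pos, pos + aln.length))
        pos += aln.length
    return Supermatrix(
        taxa, ["".join(chunks[t]) for t in taxa], parts, gap_filled=gap_filled
    )
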