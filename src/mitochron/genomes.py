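"""Mitogenome templates and strict-clock sequence evolution.

The default :class:`GenomeTemplate` follows the conserved insect mitochondrial
gene order (as in *Anopheles gambiae*): 13 protein-coding genes, 2 rRNAs,
22 tRNAs and an AT-rich control region on a circular ~15.3 kb molecule, with
the 13 CDS summing to ~11.1 kb. Coordinates are 0-based half-open internally.

Sequence evolution is forward simulation under a strict molecular clock:
substitutions only (no indels in coding regions by default), HKY-type
exchange with an optional elevated relative rate for third codon positions,
mirroring the codon-position partitioning the downstream dating model uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .timetree import TimeTree, TreeNode

__all__ = [
    "Feature",
    "GenomeTemplate",
    "Mitogenome",
    "SimulationTruth",
    "default_template",
    "random_root_genome",
    "evolve_genomes",
    "simulate_alignment",
    "PCG_NAMES",
]

NUC = np.array(list("ACGT"))
NUC_INDEX = {b: i for i, b in enumerate("ACGT")}

#: the 13 mitochondrial protein-coding genes, canonical insect order of appearance
PCG_NAMES = (
    "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

# approximate An. gambiae-like CDS lengths (bp, divisible by 3; sum 11,181)
_PCG_LENGTHS = {
    "ND2": 1026, "COX1": 1536, "COX2": 684, "ATP8": 159, "ATP6": 678,
    "COX3": 786, "ND3": 354, "ND5": 1719, "ND4": 1338, "ND4L": 297,
    "ND6": 525, "CYTB": 1137, "ND1": 942,
}

# canonical insect mt gene order: (name, type, strand, length)
_DEFAULT_ORDER = [
    ("trnI", "tRNA", "+", 68), ("trnQ", "tRNA", "-", 69), ("trnM", "tRNA", "+", 68),
    ("ND2", "CDS", "+", 1026), ("trnW", "tRNA", "+", 68), ("trnC", "tRNA", "-", 66),
    ("trnY", "tRNA", "-", 68), ("COX1", "CDS", "+", 1536), ("trnL2", "tRNA", "+", 68),
    ("COX2", "CDS", "+", 684), ("trnK", "tRNA", "+", 70), ("trnD", "tRNA", "+", 68),
    ("ATP8", "CDS", "+", 159), ("ATP6", "CDS", "+", 678), ("COX3", "CDS", "+", 786),
    ("trnG", "tRNA", "+", 66), ("ND3", "CDS", "+", 354), ("trnA", "tRNA", "+", 67),
    ("trnR", "tRNA", "+", 66), ("trnN", "tRNA", "+", 68), ("trnS1", "tRNA", "+", 67),
    ("trnE", "tRNA", "+", 67), ("trnF", "tRNA", "-", 67), ("ND5", "CDS", "-", 1719),
    ("trnH", "tRNA", "-", 68), ("ND4", "CDS", "-", 1338), ("ND4L", "CDS", "-", 297),
    ("trnT", "tRNA", "+", 66), ("trnP", "tRNA", "-", 67), ("ND6", "CDS", "+", 525),
    ("CYTB", "CDS", "+", 1137), ("trnS2", "tRNA", "+", 68), ("ND1", "CDS", "-", 942),
    ("trnL1", "tRNA", "-", 66), ("lrRNA", "rRNA", "-", 1325), ("trnV", "tRNA", "-", 72),
    ("srRNA", "rRNA", "-", 800), ("CR", "D-loop", "+", 520),
]


@dataclass(frozen=True)
class Feature:
    """Annotated interval on the circular genome, 0-based half-open."""

    name: str
    ftype: str  # CDS | tRNA | rRNA | D-loop
    start: int
    end: int
    strand: str  # '+' | '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeTemplate:
    """Gene order and coordinates for a circular mitogenome."""

    features: tuple[Feature, ...]
    length: int

    def __post_init__(self):
        for f in self.features:
            if f.ftype == "CDS" and f.length % 3 != 0:
                raise ValueError(f"CDS {f.name} length {f.length} not divisible by 3")
        ends = sorted((f.start, f.end) for f in self.features)
        for (s1, e1), (s2, _e2) in zip(ends, ends[1:]):
            if s2 < e1:
                raise ValueError("overlapping features in template")
        if not (14900 <= self.length <= 15500):
            raise ValueError(f"genome length {self.length} outside [14900, 15500]")

    @property
    def cds_features(self) -> list[Feature]:
        return [f for f in self.features if f.ftype == "CDS"]

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def third_position_mask(self) -> np.ndarray:
        """Boolean mask over the genome: True at third codon positions."""
        mask = np.zeros(self.length, dtype=bool)
        for f in self.cds_features:
            idx = np.arange(f.start, f.end)
            if f.strand == "+":
                mask[idx[2::3]] = True
            else:
                # codons read right-to-left on the minus strand
                mask[idx[::-1][2::3]] = True
        return mask


def default_template() -> GenomeTemplate:
    """The canonical insect mt gene order on a 15.3 kb circle."""
    feats = []
    pos = 0
    for name, ftype, strand, length in _DEFAULT_ORDER:
        feats.append(Feature(name, ftype, pos, pos + length, strand))
        pos += length
    return GenomeTemplate(tuple(feats), pos)


@dataclass
class Mitogenome:
    """A circular mitochondrial genome sequence with its annotation."""

    sequence: str
    template: Optional[GenomeTemplate] = None
    taxon: str = ""

    def __post_init__(self):
        allowed = set("ACGTRYSWKMBDHVN")
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(f"non-IUPAC characters in genome: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Circular-aware slice (end may exceed the genome length)."""
        L = len(self.sequence)
        length = end - start
        if length > L:
            raise ValueError("slice longer than genome")
        if length <= 0:
            return ""
        start %= L
        doubled = self.sequence + self.sequence
        return doubled[start : start + length]

    def cds(self, name: str) -> str:
        """Coding-strand CDS sequence for a named gene."""
        f = self.template.feature(name)
        seq = self.fetch(f.start, f.end)
        return seq if f.strand == "+" else revcomp(seq)

    def rotated(self, offset: int) -> "Mitogenome":
        L = len(self.sequence)
        offset %= L
        return Mitogenome(self.sequence[offset:] + self.sequence[:offset],
                          template=None, taxon=self.taxon)


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a simulation run."""

    tree: TimeTree
    rate: float = 0.0115  # substitutions/site/my
    copy_ratio: float = 55.0  # mt copies per nuclear copy
    error_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.copy_ratio < 1:
            raise ValueError("copy_ratio must be >= 1")


_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# root genome generation

#: AT-rich base composition typical of mosquito mtDNA (A, C, G, T)
DEFAULT_FREQS = (0.39, 0.12, 0.10, 0.39)

_STOPS_TABLE5 = {"TAA", "TAG"}


def _random_codons(rng: np.random.Generator, n_codons: int, freqs) -> str:
    """Sense codons under translation table 5 (no internal stops)."""
    out = []
    while len(out) < n_codons:
        draw = rng.choice(4, size=3 * (n_codons - len(out)), p=freqs)
        for i in range(0, len(draw), 3):
            codon = "".join(NUC[draw[i : i + 3]])
            if codon not in _STOPS_TABLE5:
                out.append(codon)
            if len(out) == n_codons:
                break
    return "".join(out)


def random_nuclear_background(
    length: int = 1_000_000,
    seed: Optional[int] = None,
    freqs: Sequence[float] = DEFAULT_FREQS,
) -> str:
    """Surrogate nuclear sequence for shotgun simulation (default 1 Mb)."""
    rng = np.random.default_rng(seed)
    f = np.asarray(freqs, dtype=float)
    return "".join(NUC[rng.choice(4, size=length, p=f / f.sum())])


def random_root_genome(
    template: Optional[GenomeTemplate] = None,
    seed: Optional[int] = None,
    freqs: Sequence[float] = DEFAULT_FREQS,
    taxon: str = "root",
) -> Mitogenome:
    """Draw a random genome respecting the template's coding constraints.

    CDS regions start with ATG/ATT, contain no internal stop under the
    invertebrate mitochondrial code, and end with TAA; non-coding regions are
    i.i.d. draws from the given base composition.
    """
    if template is None:
        template = default_template()
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()

    seq = list("".join(NUC[rng.choice(4, size=template.length, p=freqs)]))
    for f in template.features:
        if f.ftype != "CDS":
            continue
        n_codons = f.length // 3
        start_codon = "ATG" if rng.random() < 0.5 else "ATT"
        body = _random_codons(rng, n_codons - 2, freqs)
        coding = start_codon + body + "TAA"
        if f.strand == "-":
            coding = revcomp(coding)
        seq[f.start : f.end] = coding
    return Mitogenome("".join(seq), template=template, taxon=taxon)


# ---------------------------------------------------------------------------
# substitution process

def _hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 generator normalized to one expected substitution per unit time."""
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(freqs, np.diag(Q))
    return Q / mu


def _pmatrix(Q: np.ndarray, t: float) -> np.ndarray:
    from scipy.linalg import expm

    return expm(Q * t)


def _purge_nonsense(
    child: np.ndarray, parent: np.ndarray, template: GenomeTemplate
) -> None:
    """Revert substitutions that created internal stop codons in any CDS.

    A light stand-in for purifying selection: nonsense codons are restored to
    the parental codon, keeping every simulated gene translatable.
    """
    for f in template.cds_features:
        idx = np.arange(f.start, f.end)
        if f.strand == "+":
            codons = child[idx].reshape(-1, 3)
        else:
            codons = (3 - child[idx[::-1]]).reshape(-1, 3)
        # stops under the invertebrate mt code: TAA (3,0,0) and TAG (3,0,2)
        is_stop = (codons[:, 0] == 3) & (codons[:, 1] == 0) & (
            (codons[:, 2] == 0) | (codons[:, 2] == 2)
        )
        is_stop[-1] = False  # terminal stop is legitimate
        if not is_stop.any():
            continue
        for ci in np.nonzero(is_stop)[0]:
            if f.strand == "+":
                pos = idx[3 * ci : 3 * ci + 3]
            else:
                pos = idx[::-1][3 * ci : 3 * ci + 3]
            child[pos] = parent[pos]


def _evolve_states(
    parent: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample child states site-wise from the transition matrix rows."""
    child = parent.copy()
    u = rng.random(parent.shape[0])
    cum = np.cumsum(P, axis=1)
    for s in range(4):
        idx = parent == s
        if not idx.any():
            continue
        child[idx] = np.searchsorted(cum[s], u[idx], side="right")
    np.clip(child, 0, 3, out=child)
    return child


def evolve_genomes(
    tree: TimeTree,
    truth: SimulationTruth,
    template: Optional[GenomeTemplate] = None,
    root_genome: Optional[Mitogenome] = None,
    kappa: float = 4.0,
    third_position_rate: float = 1.0,
    seed: Optional[int] = None,
) -> dict[str, Mitogenome]:
    """Evolve one mitogenome per tip under a strict clock.

    Substitutions only; third codon positions evolve at ``third_position_rate``
    relative to all other sites, with class rates rescaled so the genome-wide
    mean equals ``truth.rate``. Returns a dict keyed by taxon label.
    """
    if template is None:
        template = root_genome.template if root_genome is not None else default_template()
    if root_genome is None:
        root_genome = random_root_genome(template, seed=seed)
    if len(root_genome.sequence) != template.length:
        raise ValueError("root genome length does not match template")

    rng = np.random.default_rng(None if seed is None else seed + 1)
    freqs = np.asarray(DEFAULT_FREQS)
    Q = _hky_rate_matrix(kappa, freqs)

    mask3 = template.third_position_mask()
    w3 = mask3.mean()
    # rescale class rates so the length-weighted mean is 1
    norm = (1 - w3) * 1.0 + w3 * third_position_rate
    r_other = 1.0 / norm
    r_third = third_position_rate / norm

    root_states = np.fromiter(
        (NUC_INDEX[b] for b in root_genome.sequence), dtype=np.int8,
        count=template.length,
    )
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    out: dict[str, Mitogenome] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        duration = node.parent.age - node.age
        parent_states = states[id(node.parent)]
        child = parent_states.copy()
        for rel, m in ((r_other, ~mask3), (r_third, mask3)):
            if truth.rate * rel * duration > 0:
                P = _pmatrix(Q, truth.rate * rel * duration)
                child[m] = _evolve_states(parent_states[m], P, rng)
        _purge_nonsense(child, parent_states, template)
        states[id(node)] = child
        if node.is_leaf:
            out[node.label] = Mitogenome(
                "".join(NUC[child]), template=template, taxon=node.label
            )
    return out


def simulate_alignment(
    tree: TimeTree,
    n_sites: int,
    rate: float,
    kappa: float = 1.0,
    freqs: Optional[Sequence[float]] = None,
    model=None,
    seed: Optional[int] = None,
) -> dict[str, str]:
    """Simulate an ungapped alignment on a dated tree under a strict clock.

    ``kappa=1`` with uniform frequencies gives JC69; alternatively pass any
    :class:`~mitochron.substmodels.SubstitutionModel` (its discrete-gamma
    categories, if set, are sampled per site). Returns taxon -> sequence.
    """
    rng = np.random.default_rng(seed)
    if model is not None:
        f = model.freqs
        pmat = model.pmatrix
        cat_rates = model.category_rates()
    else:
        f = np.full(4, 0.25) if freqs is None else np.asarray(freqs, dtype=float)
        f = f / f.sum()
        Q = _hky_rate_matrix(kappa, f)
        pmat = lambda t: _pmatrix(Q, t)
        cat_rates = np.array([1.0])

    site_cat = rng.integers(len(cat_rates), size=n_sites)
    root_states = rng.choice(4, size=n_sites, p=f).astype(np.int8)
    states = {id(tree.root): root_states}
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = rate * (node.parent.age - node.age)
        parent = states[id(node.parent)]
        child = parent.copy()
        for ci, g in enumerate(cat_rates):
            m = site_cat == ci
            if t * g > 0:
                child[m] = _evolve_states(parent[m], pmat(t * g), rng)
        states[id(node)] = child
        if node.is_leaf:
            out[node.label] = "".join(NUC[child])
    return out
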