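"""De Bruijn assembly, anchoring, IUPAC collapse and polishing."""

import numpy as np
import pytest

import mitochron as mc
from mitochron.assemble import Contig, Layout, Placement, iupac_code
from mitochron.genomes import revcomp
from mitochron.reads import ReadMultiset, ReadPair


def test_single_read_yields_expected_kmer_count():
    read = "ACGTACGGTTCAACGTGGA" * 3  # length 57
    graph = mc.build_graph([read], k=21)
    assert sum(graph.counts.values()) == len(read) - 21 + 1


def test_even_k_rejected():
    with pytest.raises(ValueError):
        mc.build_graph(["A" * 50], k=20)


def test_graph_kmers_equal_genome_kmers(assembly_roundtrip, root_genome):
    genome_graph = mc.build_graph(
        [root_genome.sequence + root_genome.sequence[:28]], k=29
    )
    read_graph = assembly_roundtrip["graph"]
    # after the coverage cutoff the surviving k-mers are exactly the genome's
    kept = {c for c, n in read_graph.counts.items() if n >= 70}
    assert kept == set(genome_graph.counts)


def test_two_overlapping_reads_connected():
    a = "ACGGTTCAACGTGGATCCAGT"
    b = a[1:] + "A"
    graph = mc.build_graph([a, b], k=21)
    contigs = mc.assemble_contigs(graph, min_kmer_coverage=1)
    assert len(contigs) == 1
    assert contigs[0].sequence in (a + "A", revcomp(a + "A"))


def test_single_copy_circle_assembles_to_one_contig(root_genome):
    # error-free single-copy circular genome, cutoff 1
    s = root_genome.sequence
    reads = [s[i : i + 80] if i + 80 <= len(s) else (s + s)[i : i + 80]
             for i in range(0, len(s), 40)]
    graph = mc.build_graph(reads, k=29)
    contigs = mc.assemble_contigs(graph, min_kmer_coverage=1)
    assert len(contigs) == 1
    recovered = mc.rotate_to_match(contigs[0].sequence[: len(s)], s)
    assert recovered == s


def test_coverage_cutoff_removes_rare_kmers():
    rng = np.random.default_rng(12)
    bases = np.array(list("ACGT"))
    deep = "".join(bases[rng.integers(0, 4, 80)])
    rare = "".join(bases[rng.integers(0, 4, 80)])
    graph = mc.build_graph([deep] * 100 + [rare], k=29)
    contigs = mc.assemble_contigs(graph, min_kmer_coverage=70)
    joined = " ".join(c.sequence for c in contigs)
    probe = rare[:29]
    assert probe not in joined and revcomp(probe) not in joined
    assert deep in joined or revcomp(deep) in joined


def test_repeat_splits_assembly_into_three_contigs():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    seg1 = "".join(bases[rng.integers(0, 4, 300)])
    seg2 = "".join(bases[rng.integers(0, 4, 300)])
    repeat = "".join(bases[rng.integers(0, 4, 60)])  # repeat longer than k
    genome = seg1 + repeat + seg2 + repeat  # circular with duplicate repeat
    doubled = genome + genome
    reads = [doubled[i : i + 90] for i in range(len(genome))]
    graph = mc.build_graph(reads, k=31)
    contigs = mc.assemble_contigs(graph, min_kmer_coverage=1)
    assert len(contigs) >= 3


def test_anchor_placements_and_overlap(root_genome):
    ref = root_genome
    c1 = Contig(ref.sequence[1000:3000], 10.0, "c1")
    c2 = Contig(revcomp(ref.sequence[2850:4600]), 10.0, "c2")
    layout = mc.anchor_layout([c1, c2], ref)
    assert not layout.unplaced
    p1, p2 = layout.placements
    assert (p1.start, p1.end, p1.strand) == (1000, 3000, "+")
    assert (p2.start, p2.end, p2.strand) == (2850, 4600, "-")
    assert layout.overlaps() == [150]


def test_unanchorable_contig_reported():
    rng = np.random.default_rng(1)
    alien = Contig("".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)]),
                   1.0, "alien")
    ref = mc.random_root_genome(seed=2)
    layout = mc.anchor_layout([alien], ref)
    assert layout.unplaced == [alien]


@pytest.mark.parametrize(
    "bases,expected",
    [({"A"}, "A"), ({"A", "G"}, "R"), ({"A", "C", "T"}, "H"), ({"A", "C", "G", "T"}, "N")],
)
def test_iupac_codes(bases, expected):
    assert iupac_code(bases) == expected


def test_collapse_disagreements_and_gaps(root_genome):
    ref = root_genome
    L = len(ref.sequence)
    a = list(ref.sequence[0:2000])
    b = list(ref.sequence[1500:3500])
    # plant a disagreement inside the overlap region
    pos = 1700
    a[pos] = "A" if ref.sequence[pos] != "A" else "G"
    layout = Layout(
        [
            Placement(Contig("".join(a), 5.0, "a"), 0, 2000, "+"),
            Placement(Contig("".join(b), 5.0, "b"), 1500, 3500, "+"),
        ],
        L,
    )
    draft, gaps = mc.collapse_layout(layout)
    assert draft[pos] == iupac_code({a[pos], ref.sequence[pos]})
    assert gaps == [(3500, L)]
    assert set(draft[3500:]) == {"N"}


def test_polish_majority_and_tie_rules():
    draft = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTA"  # 37 bp
    correct = draft[:18] + "A" + draft[19:]  # reads carry A at position 18
    reads = ReadMultiset([ReadPair(correct, correct, 0)] * 7
                         + [ReadPair(draft, draft, 0)] * 3)
    out = mc.polish(draft, reads, k_map=15, circular=False)
    assert out.sequence[18] == "A"
    assert out.corrected[18]
    # exact tie: draft base retained
    tied = ReadMultiset([ReadPair(correct, correct, 0)] * 5
                        + [ReadPair(draft, draft, 0)] * 5)
    out2 = mc.polish(draft, tied, k_map=15, circular=False)
    assert out2.sequence == draft
    assert out2.n_corrections == 0


def test_polish_resolves_ambiguity_to_majority():
    clean = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTA"
    draft = clean[:20] + "R" + clean[21:]  # ambiguous draft position
    reads = ReadMultiset([ReadPair(clean, clean, 0)] * 6)
    out = mc.polish(draft, reads, k_map=15, circular=False)
    assert out.sequence == clean
    assert out.corrected[20]


def test_polish_clean_data_needs_no_corrections(assembly_roundtrip):
    assert assembly_roundtrip["polished"].n_corrections == 0


def test_polish_second_pass_converges(assembly_roundtrip, shotgun_world):
    reads, _ = shotgun_world
    again = mc.polish(assembly_roundtrip["polished"].sequence, reads)
    assert again.n_corrections == 0


def test_roundtrip_recovers_genome_exactly(assembly_roundtrip, root_genome):
    polished = assembly_roundtrip["polished"].sequence
    assert assembly_roundtrip["gaps"] == []
    assert mc.rotate_to_match(polished, root_genome.sequence) == root_genome.sequence


def test_layout_overlap_consistency(assembly_roundtrip):
    layout = assembly_roundtrip["layout"]
    for (a, b), ov in zip(
        zip(layout.placements, layout.placements[1:]), layout.overlaps()
    ):
        assert ov == max(0, a.end - b.start)
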