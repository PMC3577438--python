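"""Masked consensus, primer-site constraints, Tm model and tiling design."""

import itertools

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as bio_mt

import mitochron as mc
from mitochron.amplicons import PrimerSite, design_tiling


@pytest.fixture(scope="module")
def aligned_genomes(root_genome):
    """Five closely-related genomes (no indels, equal length = aligned)."""
    tree = mc.simulate_time_tree(5, root_age=2.0, seed=3)
    truth = mc.SimulationTruth(tree, rate=0.0115)
    genomes = mc.evolve_genomes(tree, truth, root_genome=root_genome, seed=4)
    return [g.sequence for g in genomes.values()]


def test_identical_sequences_have_no_variants():
    cons = mc.build_masked_consensus(["ACGTACGT"] * 5)
    assert cons.variant.sum() == 0
    assert cons.sequence == "ACGTACGT"


def test_variant_column_flagged_with_majority():
    cons = mc.build_masked_consensus(["A", "A", "A", "A", "G"])
    assert cons.variant[0]
    assert cons.sequence == "A"


def test_gap_column_flagged():
    cons = mc.build_masked_consensus(["A-C", "AAC", "A-C"])
    assert cons.gap[1] and not cons.gap[0]
    # footprints over the gap column are rejected downstream
    sites = mc.scan_primer_sites(cons, len_range=(3, 3), tm_range=(-100, 200),
                                 gc_range=(0, 1), circular=False)
    assert sites == []


def test_single_sequence_rejected():
    with pytest.raises(ValueError):
        mc.build_masked_consensus(["ACGT"])


def test_nn_melting_temp_matches_reference_implementation():
    rng = np.random.default_rng(0)
    for n in (18, 22, 27):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        assert mc.nn_melting_temp(seq) == pytest.approx(
            bio_mt.Tm_NN(seq, Na=50), abs=0.01
        )


def test_conserved_consensus_accepts_all_valid_windows(root_genome):
    cons = mc.build_masked_consensus([root_genome.sequence[:600]] * 3)
    sites = mc.scan_primer_sites(cons, circular=False)
    # every accepted site satisfies the published constraints
    for s in sites:
        assert s.variant_count == 0 and s.three_prime_clean
        assert 18 <= s.length <= 27
        assert 45 <= s.tm <= 65 and 0.2 <= s.gc <= 0.6
    # and every window failing none of the constraints is present
    expected = 0
    seq = cons.sequence
    for wlen in range(18, 28):
        for i in range(len(seq) - wlen + 1):
            w = seq[i : i + wlen]
            gc = (w.count("G") + w.count("C")) / wlen
            tm = mc.nn_melting_temp(w)
            if 45 <= tm <= 65 and 0.2 <= gc <= 0.6:
                expected += 2  # both strands accepted
    assert len(sites) == expected


def test_window_with_three_variants_rejected():
    seq = "ATGCATGCATGCATGCATGCAT"
    aln = [seq, seq, seq]
    variant_pos = [3, 9, 15]
    mutated = list(seq)
    for p in variant_pos:
        mutated[p] = "A" if seq[p] != "A" else "C"
    aln.append("".join(mutated))
    cons = mc.build_masked_consensus(aln)
    assert cons.variant.sum() == 3
    sites = mc.scan_primer_sites(cons, len_range=(22, 22), tm_range=(-100, 200),
                                 gc_range=(0, 1), circular=False)
    assert sites == []  # footprint spans all three masked columns


def test_variant_in_three_prime_end_rejected():
    seq = "ATGCATGCATGCATGCATGCAT"
    mutated = seq[:-1] + ("A" if seq[-1] != "A" else "C")
    cons = mc.build_masked_consensus([seq, seq, mutated])
    sites = mc.scan_primer_sites(cons, len_range=(22, 22), tm_range=(-100, 200),
                                 gc_range=(0, 1), circular=False)
    # plus-strand site rejected (variant at its 3' terminus); minus accepted
    assert all(s.strand == "-" for s in sites)
    assert len(sites) == 1


def test_primer_site_invariants_enforced():
    with pytest.raises(ValueError):
        PrimerSite(0, 20, "+", 55.0, 0.4, 3, True, "A" * 20)
    with pytest.raises(ValueError):
        PrimerSite(0, 20, "+", 55.0, 0.4, 0, False, "A" * 20)


def test_seven_amplicon_scheme_on_default_configuration(aligned_genomes):
    cons = mc.build_masked_consensus(aligned_genomes)
    sites = mc.scan_primer_sites(cons)
    scheme = mc.design_tiling(sites, len(cons))
    assert scheme.n == 7
    assert scheme.warning is None
    scheme.validate(min_overlap=100, product_range=(2000, 3500))
    for a in scheme.amplicons:
        assert 2000 <= a.product_length <= 3500
    assert min(scheme.overlaps) >= 100


def test_genome_shorter_than_product_infeasible():
    site = PrimerSite(0, 20, "+", 55.0, 0.4, 0, True, "A" * 20)
    with pytest.raises(mc.InfeasibleTilingError):
        design_tiling([site], genome_length=1000, product_range=(2000, 3500))


def test_crafted_sparse_sites_match_exhaustive_search(root_genome):
    """When valid sites exist only at 7 evenly spaced loci, the DFS result
    equals the unique tiling found by brute-force enumeration."""
    L = 14_000
    seq = root_genome.sequence[:L]
    starts = [i * 2000 for i in range(7)]
    sites = []
    for s in starts:
        sites.append(PrimerSite(s, 20, "+", 55.0, 0.4, 0, True, seq[s : s + 20]))
        # reverse site ending 2200 after this start (product 2200)
        e = (s + 2200) % L
        sites.append(PrimerSite((e - 20) % L, 20, "-", 55.0, 0.4, 0, True, "N" * 20))
    scheme = design_tiling(sites, L, product_range=(2000, 3500),
                           min_overlap=100, n_target=7)
    assert scheme.n == 7
    got = sorted(a.forward.start for a in scheme.amplicons)
    # brute-force check: enumerate every (forward, reverse) pairing with an
    # in-range product and confirm each forward site admits exactly one,
    # so the seven-locus tiling is unique
    fwd = [s for s in sites if s.strand == "+"]
    rev = [s for s in sites if s.strand == "-"]
    for f in fwd:
        products = [
            (r.end - f.start) % L
            for r in rev
            if 2000 <= (r.end - f.start) % L <= 3500
        ]
        assert products == [2200]
    assert got == starts


def test_scheme_coverage_counts(aligned_genomes):
    cons = mc.build_masked_consensus(aligned_genomes)
    sites = mc.scan_primer_sites(cons)
    scheme = mc.design_tiling(sites, len(cons))
    covered = np.zeros(len(cons), dtype=int)
    for a in scheme.amplicons:
        idx = (a.forward.start + np.arange(a.product_length)) % len(cons)
        covered[idx] += 1
    assert covered.min() >= 1
    assert (covered >= 2).sum() >= sum(scheme.overlaps)
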