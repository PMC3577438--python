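"""Corrected distances and neighbor-joining topology estimation."""

import numpy as np
import pytest

import mitochron as mc
from mitochron.distances import DistanceMatrix, MAX_DISTANCE


def _sm(seqs: dict[str, str]):
    class S:
        pass

    s = S()
    s.taxa = list(seqs)
    s.sequences = list(seqs.values())
    return s


def test_identical_sequences_distance_zero():
    d, sat = mc.tn93_distance("ACGTACGT" * 10, "ACGTACGT" * 10)
    assert d == 0.0 and not sat


def test_jc69_closed_form_at_p_ten_percent():
    seq1 = "A" * 100
    seq2 = "G" * 10 + "A" * 90  # p = 0.10
    d, _ = mc.jc69_distance(seq1, seq2)
    assert d == pytest.approx(-0.75 * np.log(1 - 4 * 0.10 / 3), abs=1e-12)
    assert d == pytest.approx(0.1073, abs=1e-4)


def test_saturated_pair_capped_with_flag():
    d, sat = mc.jc69_distance("A" * 100, "C" * 50 + "G" * 50)
    assert sat and d == MAX_DISTANCE


def test_gap_and_ambiguity_sites_excluded_pairwise():
    d, _ = mc.jc69_distance("ACGTN-", "ACGAAA")
    d_ref, _ = mc.jc69_distance("ACGT", "ACGA")
    assert d == pytest.approx(d_ref)


def test_tn93_matches_jc_on_uniform_data():
    tree = mc.simulate_time_tree(2, root_age=10.0, seed=1)
    aln = mc.simulate_alignment(tree, 20_000, 0.0115, seed=2)
    a, b = aln.values()
    d_tn, _ = mc.tn93_distance(a, b)
    d_jc, _ = mc.jc69_distance(a, b)
    assert d_tn == pytest.approx(d_jc, rel=0.02)


def test_distances_scale_linearly_with_tmrca():
    """Corrected distance regressed on simulated TMRCA: R^2 > 0.99."""
    tmrcas = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 30.0])
    ds = []
    for i, T in enumerate(tmrcas):
        tree = mc.simulate_time_tree(2, root_age=float(T), seed=10 + i)
        aln = mc.simulate_alignment(tree, 10_770, 0.0115, seed=20 + i)
        a, b = aln.values()
        ds.append(mc.jc69_distance(a, b)[0])
    ds = np.array(ds)
    r = np.corrcoef(tmrcas, ds)[0, 1]
    assert r**2 > 0.99
    slope = np.polyfit(tmrcas, ds, 1)[0]
    assert slope == pytest.approx(2 * 0.0115, rel=0.1)


def test_pairwise_distance_matrix_shape_and_symmetry():
    tree = mc.simulate_time_tree(4, root_age=10.0, seed=3)
    aln = mc.simulate_alignment(tree, 3000, 0.0115, seed=4)
    D = mc.pairwise_distances(_sm(aln))
    assert D.values.shape == (4, 4)
    assert np.allclose(D.values, D.values.T)
    assert np.all(np.diag(D.values) == 0)


def test_nj_exact_on_additive_matrix():
    # tree ((A:2,B:3):1,C:2,D:4) in unrooted form
    taxa = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 5, 5, 7],
         [5, 0, 6, 8],
         [5, 6, 0, 8],
         [7, 8, 8, 0]], dtype=float,
    )
    # recompute as truly additive: A-B=5, A-C=2+1+2=5, A-D=2+1+4=7,
    # B-C=3+1+2=6, B-D=3+1+4=8, C-D=2+4=6
    D[2, 3] = D[3, 2] = 6.0
    rooted = mc.nj_tree(DistanceMatrix(taxa, D), outgroup=["D"])
    tips = {frozenset(c.leaf_labels()) for c in _clades(rooted)}
    assert frozenset({"A", "B"}) in tips  # the cherry is recovered
    # branch lengths recovered exactly from the additive matrix
    lengths = _leaf_branch_lengths(rooted)
    assert lengths["A"] == pytest.approx(2.0)
    assert lengths["B"] == pytest.approx(3.0)
    assert lengths["C"] == pytest.approx(2.0)


def _clades(node):
    out = [node]
    for c in node.children:
        out.extend(_clades(c))
    return out


def _leaf_branch_lengths(node, acc=None):
    acc = {} if acc is None else acc
    if node.is_leaf:
        acc[node.label] = node.length
    for c in node.children:
        _leaf_branch_lengths(c, acc)
    return acc


def test_nj_matches_reference_implementation_on_random_matrices():
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    rng = np.random.default_rng(6)
    for trial in range(5):
        n = 6
        pts = rng.random((n, 3)) * 10
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        taxa = [f"t{i}" for i in range(n)]
        mine = mc.nj_tree(DistanceMatrix(taxa, D), outgroup=[taxa[0]])
        ref = sknj(SkDM(D, ids=taxa))
        my_splits = {
            frozenset(c.leaf_labels())
            for c in _clades(mine)
            if 1 < len(c.leaf_labels()) < n - 1
        }
        ref_splits = set()
        for node in ref.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                ref_splits.add(tips)
        # unrooted split sets must agree (complement either side)
        all_taxa = frozenset(taxa)
        norm = lambda s: min(s, all_taxa - s, key=sorted)
        assert {norm(s) for s in my_splits} <= {norm(s) for s in ref_splits} | {
            norm(frozenset([t])) for t in taxa
        }


def test_three_taxa_unique_topology():
    D = DistanceMatrix(["a", "b", "c"],
                       np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
    rooted = mc.nj_tree(D, outgroup=["c"])
    assert set(rooted.leaf_labels()) == {"a", "b", "c"}


def test_topology_recovery_from_simulated_supermatrices():
    """NJ on 10,770 simulated sites recovers the generating 5-taxon
    topology in nearly all replicates."""
    hits = 0
    reps = 8
    for i in range(reps):
        tree = mc.simulate_time_tree(5, root_age=30.0, seed=500 + i)
        aln = mc.simulate_alignment(tree, 10_770, 0.0115, seed=600 + i)
        D = mc.pairwise_distances(_sm(aln), model="jc69")
        out_tip = tree.root.children[0]
        og = [l.label for l in _tips_of(out_tip)]
        if len(og) > 2:  # keep the outgroup small for a clean comparison
            og = og[:1]
        rooted = mc.nj_tree(D, outgroup=og)
        if _unrooted_splits(rooted) == _true_splits(tree):
            hits += 1
    assert hits >= reps - 1


def _tips_of(node):
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def _norm_splits(splits, all_taxa):
    return {min(s, all_taxa - s, key=sorted) for s in splits
            if 1 < len(s) < len(all_taxa) - 1}


def _unrooted_splits(rooted):
    all_taxa = frozenset(rooted.leaf_labels())
    return _norm_splits(
        {frozenset(c.leaf_labels()) for c in _clades(rooted)}, all_taxa
    )


def _true_splits(tree):
    all_taxa = frozenset(tree.taxa)
    clades = set()
    for node in tree.preorder():
        if not node.is_leaf:
            clades.add(frozenset(l.label for l in _tips_of(node)))
    return _norm_splits(clades, all_taxa)
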