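"""Pruning likelihood against closed-form and enumeration oracles."""

import itertools

import numpy as np
import pytest

import mitochron as mc
from mitochron.likelihood import compress_patterns, tree_log_likelihood
from mitochron.dating import _ClockLikelihood
from mitochron.substmodels import discrete_gamma_rates
from mitochron.timetree import TimeTree, TreeNode


def _pair_tree(age=1.0):
    root = TreeNode(age=age)
    root.add_child(TreeNode(age=0.0, label="A"))
    root.add_child(TreeNode(age=0.0, label="B"))
    return root


def _quartet():
    r = TreeNode(age=2.0)
    n1 = r.add_child(TreeNode(age=0.8))
    n2 = r.add_child(TreeNode(age=1.2))
    for n, labels in ((n1, ("t1", "t2")), (n2, ("t3", "t4"))):
        for lab in labels:
            n.add_child(TreeNode(age=0.0, label=lab))
    return r


def _brute_force(root, seqs, model, bl):
    """Sum the likelihood over every internal-state assignment."""
    nodes = [n for n in _preorder(root) if not n.is_leaf]
    leaves = [n for n in _preorder(root) if n.is_leaf]
    rates = model.category_rates()
    total = 0.0
    n_sites = len(next(iter(seqs.values())))
    logs = []
    for site in range(n_sites):
        lik = 0.0
        for g in rates:
            for assign in itertools.product(range(4), repeat=len(nodes)):
                states = {id(n): s for n, s in zip(nodes, assign)}
                for leaf in leaves:
                    states[id(leaf)] = "ACGT".index(seqs[leaf.label][site])
                p = model.freqs[states[id(root)]]
                for n in _preorder(root):
                    if n.parent is None:
                        continue
                    P = model.pmatrix(bl(n) * g)
                    p *= P[states[id(n.parent)], states[id(n)]]
                lik += p / len(rates)
        logs.append(np.log(lik))
    return float(sum(logs))


def _preorder(root):
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def test_zero_branch_identical_site_gives_log_frequency():
    root = _pair_tree(age=0.0 + 1e-12)
    seqs = {"A": "C", "B": "C"}
    pats = compress_patterns(seqs)
    model = mc.HKY(freqs=np.array([0.1, 0.4, 0.3, 0.2]), kappa=3.0)
    ll = tree_log_likelihood(root, pats, model, lambda n: 0.0)
    assert ll == pytest.approx(np.log(0.4), abs=1e-12)


def test_two_taxon_closed_form_jc():
    root = _pair_tree(age=1.0)
    seqs = {"A": "ACGTACGGTT", "B": "ACGTTCGGAT"}
    pats = compress_patterns(seqs)
    model = mc.JC69()
    rate = 0.07
    ll = tree_log_likelihood(root, pats, model,
                             lambda n: rate * (n.parent.age - n.age))
    P = model.pmatrix(2 * rate)
    expected = sum(
        np.log(0.25 * P["ACGT".index(x), "ACGT".index(y)])
        for x, y in zip(seqs["A"], seqs["B"])
    )
    assert ll == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize(
    "model",
    [
        mc.JC69(),
        mc.HKY(freqs=np.array([0.3, 0.2, 0.2, 0.3]), kappa=4.0),
        mc.HKY(freqs=np.array([0.3, 0.2, 0.2, 0.3]), kappa=4.0, alpha=0.4),
        mc.GTR(freqs=np.array([0.35, 0.15, 0.15, 0.35]),
               rates=np.array([1.5, 4.0, 0.8, 1.2, 5.0, 1.0]), alpha=0.7),
    ],
    ids=["jc", "hky", "hky_gamma", "gtr_gamma"],
)
def test_quartet_matches_enumeration(model):
    root = _quartet()
    seqs = {"t1": "ACGTAC", "t2": "AAGTTC", "t3": "CCGTAG", "t4": "ACTTAC"}
    pats = compress_patterns(seqs)
    rate = 0.3
    bl = lambda n: rate * (n.parent.age - n.age)
    ll = tree_log_likelihood(root, pats, model, bl)
    assert ll == pytest.approx(_brute_force(root, seqs, model, bl), abs=1e-8)


def test_pattern_compression_preserves_likelihood():
    tree = mc.simulate_time_tree(4, root_age=10.0, seed=8)
    aln = mc.simulate_alignment(tree, 500, 0.0115, seed=9)
    model = mc.JC69()
    bl = lambda n: 0.0115 * (n.parent.age - n.age)
    pats = compress_patterns(aln)
    assert pats.n_patterns < 500
    ll = tree_log_likelihood(tree.root, pats, model, bl)
    per_site = 0.0
    for i in range(500):
        col = {t: aln[t][i] for t in aln}
        per_site += tree_log_likelihood(tree.root, compress_patterns(col),
                                        model, bl)
    assert ll == pytest.approx(per_site, abs=1e-6)


def test_ambiguity_codes_marginalize_states():
    root = _pair_tree(age=1.0)
    model = mc.JC69()
    bl = lambda n: 0.05 * (n.parent.age - n.age)
    ll_r = tree_log_likelihood(root, compress_patterns({"A": "R", "B": "A"}),
                               model, bl)
    P = model.pmatrix(0.1)
    # R = {A, G}: leaf partial sums over both states
    expected = np.log(0.25 * (P[0, 0] + P[2, 0]))
    assert ll_r == pytest.approx(expected, abs=1e-12)


def test_fast_clock_evaluator_matches_generic_engine():
    tree = mc.simulate_time_tree(5, root_age=20.0, seed=11)
    aln = mc.simulate_alignment(tree, 2000, 0.0115, seed=12)
    pats = compress_patterns(aln)
    for model in (mc.JC69(), mc.HKY(kappa=3.0, alpha=0.5)):
        fast = _ClockLikelihood(pats, model, tree)
        generic = tree_log_likelihood(
            tree.root, pats, model,
            lambda n: 0.0115 * (n.parent.age - n.age),
        )
        assert fast.eval(0.0115) == pytest.approx(generic, abs=1e-8)


def test_two_taxon_fast_path_matches_generic():
    tree = mc.simulate_time_tree(2, root_age=12.0, seed=13)
    aln = mc.simulate_alignment(tree, 5000, 0.0115, seed=14)
    pats = compress_patterns(aln)
    fast = _ClockLikelihood(pats, mc.JC69(), tree)
    assert fast._two_taxon_jc is not None
    generic = tree_log_likelihood(
        tree.root, pats, mc.JC69(), lambda n: 0.0115 * (n.parent.age - n.age)
    )
    assert fast.eval(0.0115) == pytest.approx(generic, abs=1e-8)


def test_discrete_gamma_category_rates_average_to_one():
    for alpha in (0.2, 0.5, 1.0, 5.0):
        rates = discrete_gamma_rates(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(rates) > 0)


def test_partitioned_likelihood_sums_over_classes(root_genome):
    a1 = mc.codon_align({t: root_genome.cds("ND3") for t in "ab"}, "ND3")
    sm = mc.concatenate([a1])
    root = _pair_tree(age=5.0)
    root.children[0].label, root.children[1].label = "a", "b"
    models = [mc.JC69(), mc.JC69()]
    bl = lambda n: 0.01 * (n.parent.age - n.age)
    total = mc.partitioned_log_likelihood(sm, root, models, bl,
                                          relative_rates=[1.0, 3.0])
    seqs = dict(zip(sm.taxa, sm.sequences))
    part = 0.0
    for cls, rel in ((0, 1.0), (1, 3.0)):
        cols = sm.class_columns(cls)
        sub = {t: "".join(seqs[t][i] for i in cols) for t in seqs}
        part += tree_log_likelihood(root, compress_patterns(sub), mc.JC69(),
                                    lambda n, rel=rel: bl(n) * rel)
    assert total == pytest.approx(part, abs=1e-8)
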