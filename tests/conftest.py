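"""Shared fixtures: one synthetic mitogenome world reused across test modules.

The expensive artifacts (root genome, translated references, evolved tip
genomes, a deep shotgun read set and its assembly) are session-scoped so the
whole suite pays for them once.
"""

import numpy as np
import pytest

import mitochron as mc


@pytest.fixture(scope="session")
def root_genome():
    return mc.random_root_genome(seed=7, taxon="anc")


@pytest.fixture(scope="session")
def protein_refs(root_genome):
    return mc.ProteinReference.from_genome(root_genome)


@pytest.fixture(scope="session")
def evolved_world(root_genome):
    """Four tip genomes on a dated tree, moderate divergence."""
    tree = mc.simulate_time_tree(4, root_age=15.0, seed=3)
    truth = mc.SimulationTruth(tree, rate=0.0115)
    genomes = mc.evolve_genomes(tree, truth, root_genome=root_genome, seed=4)
    return tree, truth, genomes


@pytest.fixture(scope="session")
def gene_hits(evolved_world, protein_refs):
    """Extracted CDS per gene per taxon from the evolved genomes."""
    _, _, genomes = evolved_world
    per_gene: dict[str, dict[str, str]] = {}
    missing_all = {}
    for taxon, genome in genomes.items():
        hits, missing = mc.extract_genes(genome, protein_refs)
        missing_all[taxon] = missing
        for h in hits:
            per_gene.setdefault(h.gene, {})[taxon] = h.cds
    return per_gene, missing_all


@pytest.fixture(scope="session")
def shotgun_world(root_genome):
    """Deep error-free shotgun reads (500X mt, ~9X nuclear) with truth labels."""
    rng = np.random.default_rng(99)
    background = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60_000)])
    reads = mc.shotgun_reads(
        {"anc": root_genome}, background, copy_ratio=55.0, mean_coverage=500.0,
        read_len=100, seed=11,
    )["anc"]
    return reads, background


@pytest.fixture(scope="session")
def assembly_roundtrip(root_genome, shotgun_world):
    """Full enrich -> assemble -> anchor -> collapse -> polish pass."""
    reads, _ = shotgun_world
    enriched, report = mc.select_duplicated_reads(reads)
    graph = mc.build_graph(enriched, k=29)
    contigs = mc.assemble_contigs(graph, min_kmer_coverage=70)
    layout = mc.anchor_layout(contigs, root_genome)
    draft, gaps = mc.collapse_layout(layout)
    polished = mc.polish(draft, reads)
    return {
        "report": report,
        "graph": graph,
        "contigs": contigs,
        "layout": layout,
        "draft": draft,
        "gaps": gaps,
        "polished": polished,
    }
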