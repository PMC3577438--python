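# mitochron

Mitochondrial genomes are present in hundreds of copies per cell, which makes
them both easy to sequence deeply and awkward to assemble from whole-genome
shotgun data mixed with nuclear reads. `mitochron` implements the full
computational path used to turn such data into dated phylogenies of closely
related mosquito species (and other insects with the conserved mitochondrial
gene order): copy-number read enrichment, de novo assembly with reference
anchoring and majority-vote polishing, design of universal long-range tiling
primers from a variant-masked consensus, translated extraction and
codon-aware alignment of the 13 mitochondrial protein-coding genes into a
partitioned supermatrix, and Bayesian divergence-time estimation under a
strict molecular clock.

It is aimed at molecular ecologists and phylogeneticists who want a tested,
scriptable re-implementation of this organelle workflow, plus a synthetic
data generator that produces reads, genomes and dated trees with known truth
for validating every step.

## The models at the core

**Read enrichment by copy number.** At ~500X mitochondrial versus ~10X
nuclear coverage, an exact duplicate read is almost certainly mitochondrial:
`select_duplicated_reads` keeps reads whose sequence occurs ≥ 2 times, and
`abundance_filter_dedup` keeps one instance of each sequence seen in
strictly more than 20 reads (the multiplex variant).

**Assembly.** A canonical-k-mer de Bruijn graph (odd k, default 29) with a
coverage cutoff C (default 70) yields maximal non-branching contigs; contigs
are anchored to a reference mitogenome by exact-match diagonals, overlaps
collapsed with minimal IUPAC ambiguity codes, and the draft polished by
replacing any base contradicted by a strict majority (> 50%) of mapped
reads.

**Dating.** For taxa evolving under a strict clock with rate μ
(substitutions/site/my), a corrected pairwise distance d estimates the
divergence time as T = d / (2μ); the default insect mtDNA rate is
μ = 0.0115. The Bayesian alternative, `ClockDatingModel`, is a
statsmodels-style model object: node ages θ of a fixed rooted topology carry
order-constrained uniform priors, optionally with a Normal(260, 8.42) root
calibration (the Drosophila–Anopheles split, central 95% mass 243–276 mya),
and the likelihood is the Felsenstein pruning likelihood of the alignment
under JC69/HKY/GTR (+Γ) with branch lengths μ·Δt. `fit()` runs
Metropolis–Hastings over node ages (and μ when free) and returns a
`DatingResults` with posterior means, central 95% credible intervals and
autocorrelation-based effective sample sizes.

## Worked example

```python
import mitochron as mc

# truth: two species that split 10 mya
tree = mc.simulate_time_tree(2, root_age=10.0, seed=2)
aln = mc.simulate_alignment(tree, n_sites=10_770, rate=0.0115, seed=3)

# closed-form fixed-rate dating
a, b = aln.values()
d, _ = mc.jc69_distance(a, b)
print(f"corrected distance: {d:.4f}")
print(f"fixed-rate TMRCA:   {mc.rate_date(d):.2f} mya")

# Bayesian strict-clock dating on the same data
model = mc.ClockDatingModel(aln, tree, clock=mc.ClockModel(rate=0.0115),
                            root_max=200.0)
res = model.fit(chain_length=50_000, n_runs=1, seed=4)
print(res.summary().to_string(index=False))
```

Output:

```
corrected distance: 0.2349
fixed-rate TMRCA:   10.21 mya
node      mean  ci_2.5%  ci_97.5%        ess
root 10.213801 9.763111 10.665542 504.999974
```

The corrected distance (~0.23 substitutions/site) divided by twice the clock
rate gives the point estimate; the sampler returns the same value with a
credible interval whose width reflects the binomial information in 10,770
sites, and an effective sample size indicating how many independent
posterior draws the chain produced.

The same objects drive the pipeline end to end: `shotgun_reads` →
`select_duplicated_reads` → `build_graph`/`assemble_contigs` →
`anchor_layout`/`collapse_layout`/`polish` reconstructs a simulated
mitogenome exactly, and `extract_genes` → `codon_align` → `concatenate`
produces the partitioned supermatrix the dating model consumes. A `mitochron`
command-line tool wraps each stage (`simulate`, `enrich`, `assemble`,
`design-primers`, `annotate`, `tree`, `date`).

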