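# Methods

This note documents the models, parameter choices and numerical decisions
behind `mitochron`, and what the synthetic-data validation does and does not
establish about real data.

## Synthetic data generator

`simulate_time_tree` draws a Yule (pure-birth) tree: exponential waiting
times at per-lineage rate λ (default 1 /my), a uniformly chosen lineage
splitting at each event. Internal node depths are rescaled affinely so the
first split sits exactly at the requested root age — i.e. trees are
conditioned jointly on tip count and root age, preserving the Yule ranking
of node ages. Tips sit at age 0; ultrametricity is structural.

The default `GenomeTemplate` follows the conserved insect mitochondrial
gene order: 13 protein-coding genes (11,181 bp total), 2 rRNAs, 22 tRNAs and
a control region on a 15,314 bp circle, within the 14.9–15.5 kb range of
sequenced anopheline mitogenomes. Root genomes are drawn AT-rich
(A=T=0.39, C=0.12, G=0.10), with every CDS forced to start ATG/ATT, end
TAA, and contain no internal stop under the invertebrate mitochondrial code
(translation table 5).

`evolve_genomes` runs substitution-only forward simulation under a strict
clock (HKY exchange, default κ=4, third codon positions at a configurable
relative rate, class rates normalized so the genome-wide mean equals μ).
Substitutions that would create an internal stop codon are reverted to the
parental codon — a minimal stand-in for purifying selection that keeps every
simulated gene translatable. Indels are not simulated by default (the
supermatrix workflow assumes a fixed gene complement); an insertion path is
exercised in tests by editing CDS directly.

`shotgun_reads` samples read pairs uniformly from the circular mitogenome
and a linear nuclear background in proportion to the mt:nuclear copy ratio
(default 55, in the 50–60-fold band observed for mosquito data), at a
default 500X mitochondrial coverage, 100 bp mates, ~300 bp inserts
(SD 30). Sequencing error is uniform base substitution; qualities are
constant Q30. Not emulated: GC/amplification bias, platform error profiles,
heteroplasmy, chimeras. Consequently, passing the round-trip tests shows the
algorithms are correct on idealized reads, not that the pipeline is robust
to real instrument artifacts.

## Enrichment

Multiplicity is counted on exact full-length mate sequences, each mate
independently; reverse complements are not collapsed (both behaviours are
option flags, off by default, since the original heuristics operate on raw
read identity). A pair is retained when either mate passes
(`require_pair_concordance` demands both). The abundance filter is strict
(`count > 20`), and emits one instance per surviving sequence, sorted for
determinism. The copy-ratio diagnostic assigns reads to marker genes by
exact k-mer matching (default k=31, both strands) and reports the per-bp
coverage quotient; zero nuclear coverage is reported as infinite with a
warning flag rather than an error.

## Assembly

k-mers are canonicalized to the lexicographic minimum of the strand pair;
odd k is enforced so no k-mer is self-reverse-complementary. The coverage
cutoff `min_kmer_cov` (default 70) is applied to canonical counts before
unitig extraction; on deduplicated multiplex input the cutoff should be 1.
Contigs are maximal non-branching paths (unique successor with unique
predecessor); a walk returning to its start emits a circular contig.

Anchoring votes over exact seed matches (length 20, both strands, doubled
reference for circularity) grouped by diagonal; the winning diagonal places
the contig, and contigs with no seed hit are reported unplaced. Collapse
writes each placed base onto reference coordinates modulo the reference
length: unanimous bases pass through, disagreements become the minimal
IUPAC code covering the observed set, uncovered positions become N and are
returned as gap intervals (the stand-in for wet-lab gap filling is this gap
report). Polishing maps each mate by its first 31-mer (exact seed, both
strands, ungapped extension, circular wrap) and replaces a draft base only
where an alternative is carried by a strict majority of covering reads;
exact ties keep the draft (a "majority" that does not exist cannot replace),
ambiguous draft bases are resolved by the same strict-majority rule, and
zero-coverage positions are flagged untouched. One polishing pass is the
default; on error-free data a second pass is provably a no-op and is tested
as such.

## Primer design

Consensus masking flags any column with ≥ 2 distinct unambiguous bases, and
separately any gap-containing column; both are excluded from primer
footprints. A window is an acceptable primer site when it has ≤ 2 masked
columns, none within the last 3 bases of its 3' end (checked per strand;
the "3" is configurable), length 18–27, Tm within 45–65 °C and GC within
0.20–0.60. Melting temperatures use the unified nearest-neighbor
parameters with the 0.368·(N−1)·ln[Na+] entropy correction at 50 mM Na+ and
12.5 nM effective duplex concentration, vectorized over all windows; the
implementation is cross-checked against Biopython's `Tm_NN` in the tests.
The Tm model is configuration, not science — any monotone thermodynamic
score would serve the tiling search equally.

Tiling is a depth-first search with backtracking over (forward, reverse)
site pairs: products must lie in 2.0–3.5 kb, consecutive amplicons overlap
by ≥ 100 bp, and the scheme must close the circle. Candidates are explored
nearest-to-ideal-spacing first (ideal = (L + n·overlap)/n), with a branch
cap and an expansion budget; if no scheme with the target count (default 7,
which a ~15.3 kb circle admits under the default product range) exists, the
feasible count closest to the target is returned with a warning, and full
infeasibility raises an error carrying the largest site-free interval.
Every emitted scheme re-verifies all site and coverage invariants.

## Gene extraction and alignment

The 13 proteins are located by local alignment (BLOSUM62, gap open 10,
extend 0.5) of reference amino-acid sequences against all six frames of the
doubled genome (so genes may span the origin), under translation table 5.
The best-scoring locus per gene is reported; a best score below 30% of the
reference self-score marks the gene missing rather than silently dropping
it. Because references carry only the protein span, a trailing TAA/TAG is
appended to the hit when present, which makes self-annotation coordinate-
exact. Terminal partial stops and overlapping gene ends are handled by the
aligned-span trimming itself (the reported CDS is always in frame).

Codon alignment translates each CDS (internal stops are an error naming
taxon and codon), aligns proteins by a center-star strategy — the sequence
with the greatest summed 3-mer similarity anchors pairwise global
alignments, merged on its coordinates ("once a gap, always a gap") — and
back-translates gaps as whole codons. This guarantees frame preservation
and exact ungapping, at some cost in alignment optimality relative to full
progressive refinement; for the low-divergence congeneric data this
workflow targets, the difference is immaterial and is not modelled further.
Concatenation fills genuinely missing genes with gaps (recorded), and
annotates every column with its gene and codon-position class (1+2 vs 3),
the partitioning used downstream.

## Distances, topology, likelihood, model choice

Pairwise distances use TN93 (empirical pair frequencies, optional gamma
correction via the usual power transform), with JC69 as the uniform special
case; sites with gaps or ambiguity in either sequence are excluded
pairwise, and saturated pairs are capped at distance 5.0 and flagged.
Neighbor-joining is the classical algorithm, rooted on the branch to the
outgroup's attachment (with a warning when the outgroup is not monophyletic
in the unrooted tree); it is exact on additive matrices and cross-checked
against scikit-bio's implementation.

The likelihood engine compresses alignments to unique site patterns and
runs Felsenstein pruning with per-node rescaling; IUPAC codes and gaps
contribute over their compatible states. Discrete-gamma heterogeneity uses
4 equal-probability categories with exact category means. Partitioned
(SRD06-style) likelihoods sum per-class pruning passes with a free relative
rate for the third-position class. Model selection ML-fits {JC69, HKY,
HKY+G, GTR, GTR+G} by L-BFGS-B on log-transformed branch lengths and
parameters, with empirical base frequencies; frequencies count as 3 free
parameters (except JC69) and one rooted branch is discounted as redundant,
following the usual model-selection conventions. Non-converged fits are
flagged and excluded from the AIC choice.

## Dating model

The sampler fixes the topology and moves node ages: non-root ages are
redrawn uniformly within their (parent, oldest-child) bounds — a symmetric
proposal whose support does not depend on the current value — and the root
age takes a Gaussian walk (default step 2 my). When the clock rate is free
it takes a multiplicative move with the appropriate Hastings factor and a
log-uniform prior, and requires a root calibration to be identifiable. The
node-age prior is order-constrained uniform with either the calibration
density (Normal, mean 260 mya, SD 8.42 so that 243–276 mya is the central
95% mass; hard truncation optional and off by default, since a stated range
can denote either) or a diffuse uniform [0, root_max] at the root. A
relaxed clock and topology moves are deliberately out of scope: congeneric
mitogenome data of this kind shows little clock departure, and the fixed
NJ topology isolates the quantity of interest (node ages). Real-data node
ages from a relaxed-clock, topology-sampling analysis are therefore
expected to be near, not identical to, this sampler's output.

Chains default to 3 runs × 200,000 iterations sampled every 100 with 10%
burn-in — a 1/100-scale desk analogue of the conventional 3 × 20M/1,000
setup. Runs restart from identical initial ages, so equal seeds give
byte-identical traces; post-burn-in samples are pooled and per-run ESS is
available. Summaries report posterior means and central 2.5–97.5% quantile
intervals (explicitly not HPD), with ESS from ArviZ's autocorrelation
estimator and a warning at ESS ≤ 200. A likelihood-off mode samples the
prior alone; on a two-taxon tree the root marginal is then exactly the
calibration density, which the prior-recovery test exploits (on larger
trees the order-constraint volume tilts the root marginal, so prior
recovery is only checked where the marginal is known in closed form).

## Validation scale and benchmark choices

The recovery benchmarks (`mitochron.benchmarks`) simulate and date under
JC69 with homogeneous site rates: recovering a known age to within
Monte-Carlo error requires the estimator's correction to match the
generating process exactly, and the clock calibration being tested is
independent of which reversible model generated the data. Problem sizes —
50 two-taxon replicates for fixed-rate recovery, 20 five-taxon replicates
at 200,000 iterations for sampler recovery, 100 replicates at 50,000
iterations for interval coverage, 10,770 sites throughout (the length of
the 13-gene supermatrix) — are single-CPU choices; the test suite runs
reduced replicate counts of the same checks with tolerances scaled by the
replicate standard error. Benchmarks that require downloading published
genome accessions (whole-genome annotation against real reference proteins,
the 29-taxon supermatrix) are exposed as library entry points operating on
local GenBank/FASTA files and validated here on synthetic genomes following
the same code path.

## Known limitations

- The assembler has no paired-end scaffolding or bubble popping; repeats
  longer than k fragment the assembly by design.
- Polish mapping is exact-seed + ungapped extension; reads whose first
  k-mer overlaps an error or an indel do not map.
- Center-star protein alignment can be suboptimal for deep divergences.
- The primer search scores no dimer/hairpin thermodynamics.
- The dating model assumes a strict clock and fixed topology; rate
  variation across lineages biases its intervals narrow.
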