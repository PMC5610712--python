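# Methods

## The synthetic panel generator

The generator emulates the structure of a sequenced single-species strain
panel rather than its sequence content. Each panel has:

- `n_core` single-copy core families present in every strain;
- accessory families given as `(prevalence, n_families)` pairs, each
  family present in exactly `prevalence` strains (2 ≤ prevalence ≤ N−1),
  carriers drawn uniformly;
- `n_unique_per_genome` prevalence-1 families per strain;
- a replicon architecture per strain (one chromosome, by default one
  repA-type megaplasmid and one small plasmid), with each family allocated
  once to a replicon class (core families mostly chromosomal, accessory
  families megaplasmid-biased) so a family sits on the same class in every
  carrier.

Genes are random codon strings (ATG + sense codons + TAA) with family
lengths drawn uniformly within ±40% of the mean (`gene_length`, default
150 codons ≈ a typical bacterial CDS). Divergence is star-wise: one
ancestral sequence per family, each strain's copy mutated independently at
`substitution_rate` per site (every mutation changes the base), so two
copies differ at ≈ 2r(1 − 2r/3·…) ≈ 1 − (1−r)² of sites and direct
mutants of a sequence differ at exactly r in expectation. Codons that
mutate into stops are reverted to the ancestral codon (a ~3/61 per-hit
distortion) so every copy translates cleanly. Replicons are gene
concatenations with 100 nt spacers; spacers are ancestral per family and
mutated at the same rate, keeping intergenic divergence analytic too.

What the generator does **not** emulate: indels and rearrangements,
horizontal transfer histories, codon/composition bias, assembly
fragmentation beyond the replicon structure, multi-copy paralogs, and
pseudogenes. Passing tests therefore demonstrate algorithmic correctness
under a clean divergence model, not robustness to the full messiness of
real assemblies.

Default study conditions for end-to-end checks: 12 genomes, 300 core
families, accessory spec [(2, 40), (6, 40), (11, 20)], 15 unique genes per
genome, substitution rate 0.02 — a panel size at which ortholog inference,
rarefaction and profiling all run in minutes on one CPU while exercising
every prevalence class.

## Similarity search

Local alignment uses BLOSUM62 with gap open 11 / extend 1; raw scores are
converted to bits with the standard gapped Karlin–Altschul constants for
this scheme (λ = 0.267, K = 0.041) and e-values use database size = total
subject residues. Only identity (≥ 40%), query coverage (≥ 50% of the
query length, measured as the aligned span) and bit score (≥ 50 for
orthologs, ≥ 60 for annotation transfer) gate hits. A k-mer seed
prefilter (k = 5, ≥ 2 shared seeds) selects candidate pairs BLAST-style; at
the within-species identities this pipeline targets (≥ ~60%) it is
lossless in practice, and `prefilter=False` performs the exhaustive scan.
Exact-match seeding loses sensitivity below roughly 50% identity, which is
below every threshold used here.

## Ortholog clustering

RBB edges are weighted by the mean of the two directed best-hit bit
scores (the directed scores differ only through query length in the
coverage gate). Markov clustering runs per connected component on the
column-stochastic weight matrix with expansion 2 and inflation 3,
converging when the largest entry change is < 1e-6 (cap 100 iterations).
Self-loops with weight equal to each node's maximum incident edge weight
are added first: without them a two-node component alternates with period
two and never converges. Attractor rows define clusters; nodes claimed by
several attractor systems join the one holding the largest mass, ties
resolved toward the lexicographically smallest attractor. Clusters below
the minimum size (2) dissolve into singletons, which the presence/absence
matrix appends as prevalence-1 columns so unique genes still enter the
pan-genome accounting. Note that inflation 3 clusters by *weight
structure*: a clique whose edge weights vary several-fold can legitimately
split; within-family RBB weights are near-homogeneous, so on truth
families the two-stage clustering reduces to connected components.

## Rarefaction and the openness test

Genome addition orders are sampled uniformly with replacement from the N!
permutations (1000 by default); an explicit order set can be forced, which
makes exhaustive enumeration on small panels exact. Per permutation the
core counts are cumulative intersections and the pan counts cumulative
unions; new(k) = pan(k) − pan(k−1) with new(1) = the first genome's family
count. Medians (not means) summarise across permutations. The Heaps fit
is OLS of log10(median new) on log10(k) over k = 2..N — the first genome
is a full complement, not a discovery increment — with α = −slope; the
fit range is explicit in the output and the fit refuses ranges containing
non-positive medians. Quantiles throughout (including per-replicon gene
summaries) use linear interpolation between order statistics, which is
what produces fractional medians such as 47.5.

## ANI and POCP

ANI follows the classic fragment algorithm: 1020 nt consecutive fragments
(a trailing fragment is kept if ≥ 100 nt), each aligned to the other
genome, retention at ≥ 30% identity over ≥ 70% of the fragment, directed
ANI = mean retained identity, reported ANI = mean of both directions
(switchable). Fragment placement is two-stage: an infix edit-distance scan
(edlib, both strands) locates the best candidate region; if the implied
identity is ≥ 80% the whole fragment clearly aligns and the edit-distance
identity is used directly, otherwise a blastn-scored local alignment
(match 2, mismatch −3, gap open 5 / extend 2) on the candidate region
(±50 nt margin) supplies identity and coverage. The second stage is what
rejects unrelated sequences: the best *infix* alignment of random DNA
still shows ~50–60% identity, but its best *local* alignment covers far
less than 70% of the fragment. Results with fewer than 20 retained
fragments in either direction are flagged unreliable but still reported.

POCP applies the published formula ((C1+C2)/(T1+T2))·100 with e-value
≤ 1e-5, identity ≥ 40% and coverage > 50% of the query length; coverage is
always measured against the query's full length. The formula is symmetric
by construction, which the tests verify against a brute-force all-pairs
alignment scan.

Metric matrices are clustered by complete linkage on Euclidean distances
between similarity rows (as heatmap figures do), not on 100 − ANI; this
affects merge heights, never the topology. Labels are sorted before
clustering so tied merges resolve deterministically.

## Core phylogeny

Concatenation uses families with exactly one member in every strain, in
sorted family-id order; violations are excluded with a logged count. The
aligner is pluggable (`passthrough_align` for equal-length inputs — exact
for the generator's star-wise families — and a mafft wrapper for the
general case). Gap stripping keeps exactly the columns where no sequence
has a gap. SNP distances are case-insensitive Hamming counts on the
gap-free alignment; both amino-acid and nucleotide concatenations are
supported and the alphabet is recorded on the alignment object.

Trees are neighbor joining with deterministic tie-breaking (smallest Q,
then lexicographic label pair). Negative branch lengths are clamped to
zero with the deficit moved to the sibling branch; internal edges of
length ≤ 1e-12 are collapsed, so uninformative data yields a star rather
than an arbitrary resolution. Bootstrap replicates resample columns with
replacement and supports are the percentage of replicates containing each
internal bipartition of the full-data tree. Rooting places the root on
the outgroup's pendant edge (midpoint); a display flag may shorten the
root branch in plots but Newick distances are never altered.
Maximum-likelihood inference is deliberately out of scope — the alignment
can be exported as FASTA and any external tree read back as Newick.

## Replicon assignment and profiling

Contig assignment is markers-first: a repA/repE/parA marker at ≥ 93%
identity over its full length calls the repA-type megaplasmid class.
Otherwise the contig is fragmented (1020 nt) and each fragment matched
against each class's reference sequences at a ≥ 70% identity retention
threshold; the class with the greatest fragment coverage wins, and a best
coverage below the homology floor (default 0.1, a documented choice rather
than a derived value) leaves the contig unassigned. This reconstructs a
marker-plus-homology procedure whose exact original thresholds are not
fully specified; everything is configurable.

Cluster presence (e.g. a 21-gene exopolysaccharide operon) is called per
reference gene from transferred labels, with the cluster-level call
requiring ≥ `min_genes` matches (default 18, boundary inclusive); the
observed order of matched genes is emitted for synteny inspection rather
than hard-coding any sub-grouping. Functional count matrices tabulate one
count per labelled gene under its single best-scoring label, grouped by
strain and replicon class; proportions normalise within each
(strain, class) row, and a strain with no replicon of a class simply has
no row.

## Gene-call reconciliation and motif scanning

Predictors that disagree on a start site are merged on (strand, stop-side
coordinate) — stop codons anchor prokaryotic calls — keeping the longest
extent; single-predictor calls are retained to minimise false negatives.
The LPXTG sorting-signal scan requires the L-P-x-T-G pattern to lie wholly
within the C-terminal 50 residues (configurable); sortase-substrate
biology places the signal at the C-terminus, and matches elsewhere are
ignored.

## Problem sizes and determinism

Acceptance-scale runs use the 12-genome panel above (~4300 genes), 1000
rarefaction permutations, 100 Heaps-recovery simulations, a 200 kb genome
with 10 mutation seeds for the ANI divergence check (50 kb genomes for the
rate-monotonicity sweep), 100 bootstrap replicates, and 50 random
alignments for the SNP oracle. Every stochastic step takes an explicit
seed and is bit-reproducible; `scripts/acceptance.py` derives all of its
seeds from its `--seed` argument.

## Known limitations

- The search engine's seed prefilter is heuristic below ~50% identity;
  exhaustive mode exists but is quadratic in proteome size.
- The generator's clean substitution model means ANI/identity expectations
  are exact; real data with indels and repeats will show lower fragment
  coverage and retention.
- NJ is a distance method; branch supports are supports of the NJ
  topology, not of a likelihood model.
- Quartet-based paralog discrimination is not implemented; multi-copy
  genes binarise in the matrix and are excluded from core concatenation.
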