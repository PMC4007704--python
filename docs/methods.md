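# Methods

This note documents the models and procedures implemented in pankit, the
parameters that matter, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Gene families from similarity hits

Input hits are directed pairwise protein alignments in the 14-column extended
BLAST tabular dialect (standard 12 columns plus query and subject lengths).
Three filters are applied (`families.filter_hits`):

- `max_evalue` (default 1e-4),
- `min_identity` (default 50%),
- coverage: alignment length ≥ `min_cov_frac` (default 0.5) of *either*
  protein, i.e. of the shorter of the two. This is the permissive reading of
  "50% of either protein sequence"; it equals
  `aln ≥ min_cov_frac · min(q_len, s_len)`.

An undirected edge exists only when passing hits exist in both directions
(bidirectionality is the reciprocal-hit requirement usual in orthology
pipelines). Edge weight is `min(200, −log10(best E))`, the best E-value over
both directions, with E = 0 mapped to the 200 cap. An identity-based
weighting would also be defensible; the −log10(E) transform is the common
choice for MCL on BLAST graphs and is what we adopt.

**MCL** (`families.mcl_cluster`) follows the canonical scheme: build a
column-stochastic matrix from the weighted adjacency with self-loops set to
each node's maximum incident edge weight (1 for isolated nodes); iterate
expansion (matrix squaring), inflation (entrywise power, default 1.8, then
column renormalization) and pruning of entries below 1e-8 (the column maximum
is always kept, so no column can vanish); stop when the maximum absolute
entry change falls below 1e-6 or after 100 iterations (non-convergence is
logged and the current partition returned). Clusters are the connected
components of the limit matrix's non-zero pattern. Because flow cannot cross
between connected components of the input graph, MCL runs densely per
component; on protein-family graphs components are small, so this is both
exact and fast. Inflation 1.8 sits in the standard 1.4–2.0 range; no inflation
value is canonical, so it is exposed in configuration.

Classification: a family is *core* when present in every panel genome,
*unique* when present in exactly one, *dispensable* otherwise. Genes with no
passing hits become singleton (unique) families rather than being dropped, so
the families always partition the gene set. Single-copy *orthologues* are
core families with exactly one member per genome and no mobilome-annotated
member; mobilome families are excluded from the orthologue pool only — they
still count in pan-genome accounting, since mobile elements dominate unique
genes in real panels. Mobilome detection is a case-insensitive annotation
keyword match (transposase, IS element, insertion sequence, integrase, phage,
mobile element); the keyword list is configurable because no algorithmic
definition of the mobilome is available at this level.

## Pan-/core-genome accumulation and Heaps' law

For an ordering of the G genomes, pan(N) counts families present in at least
one of the first N genomes and core(N) those present in all of them;
new(N) = pan(N) − pan(N−1). Presence means copy count ≥ 1 — paralogues do not
inflate pan counts. All G! orderings are used when G ≤ `exhaustive_max`
(default 8); otherwise `n_permutations` (default 1000) seeded uniform random
orderings. Per-N summaries are **medians** (means are more outlier-sensitive
on small panels); for an even number of orderings the lower of the two middle
values is taken, a deterministic convention that keeps medians integral.
Monotonicity per ordering and the permutation-independence of pan(G) and
core(G) are asserted on every run.

Three models are fitted (`pangenome.fit_models`):

- new-gene decay: `new(N) = κ·N^(−α)`, ordinary least squares of
  log median_new on log N for N = 2..G (new(1) is undefined; zero medians are
  skipped in the log domain);
- pan growth: `pan(N) = κ_p·N^γ`, same log-log regression over N = 1..G;
- core decay: `core(N) = A·exp(−(N−1)/τ) + Ω`, nonlinear least squares
  (SciPy `curve_fit`) initialized at Ω ← core(G), A ← core(1) − Ω, τ ← 2;
  non-convergence is logged and the initial parameters reported.

The **openness call** follows the standard Heaps'-law criterion: α > 1 ⇒
closed (the new-gene series converges), α ≤ 1 ⇒ open. The reported "average
new-gene rate over the first k iterations" is the mean of median_new(N) for
N = 2..k+1 (default k = 9).

Note a structural property of the synthetic generator: with a fixed number of
unique families per strain, new(N) has a constant floor, so Heaps fits on
default synthetic panels give α < 1 (open). That is the correct behaviour for
that generative model; the closed-call logic is validated on curves generated
from the power law itself (α = 1.4 recovered to ~1e-6 on exact curves and to
≤ 0.1 under ±10% multiplicative noise).

## G+C deviation and variable regions

Per-ORF G+C is computed on the nucleotide sequence with N bases excluded from
numerator and denominator (ambiguity-safe); an all-N sequence is an error.
Genes with G+C strictly above `high_threshold` (68.0) or strictly below
`low_threshold` (49.0) are flagged — strict inequalities, so boundary values
are unflagged. These defaults correspond to a ~58% G+C background, where both
thresholds sit ≥ 4–5 combined standard deviations from typical gene-level
variation.

Flagged genes are merged per contig into variable regions when separated by
at most `max_gap_genes` (default 5) unflagged genes; regions with fewer than
`min_genes` (default 5) flagged members are discarded. The gene-gap rule (as
opposed to a base-pair window) makes aggregation independent of intergenic
spacing; only the outcome of such an aggregation (a handful of variable
regions containing most deviant genes) is constrained by real panels, so both
parameters are exposed. Region span runs from the first to the last flagged
member; unflagged genes inside the span are listed as members but not counted.
Summary fractions: families with ≥ 1 flagged member (family-level deviation —
any-member aggregation, the natural choice when family members share origin),
and flagged genes lying inside regions.

## Gene-trait matching

OD600 24-h endpoint readings are binarized at `cutoff` (default 0.3), with
the boundary counting as growth (the direction of the boundary is a
convention; it is recorded in the output). Families are restricted to the
assayed strains and binarized; constant patterns (all-present core, all-absent)
are set aside and reported separately since they cannot discriminate. The
default clustering mode groups families by **identical** pattern, numbered
Cluster1..K in order of first appearance. An opt-in `hcl` mode coarsens
patterns by average-linkage agglomeration on Hamming distance (SciPy), cut at
`cut_height` in strain units (0 reproduces exact grouping); merged clusters
take the majority pattern with ties resolved to presence.

The matching distance between a cluster pattern and a sugar's growth column
is the plain Hamming distance (number of disagreeing strains). Sugars with
constant growth across strains are unmatchable and excluded. Per sugar,
clusters are ranked by ascending distance, ties sharing the lower rank with
deterministic ordering by cluster id. The anti-match distance
(n_strains − d, perfect for absence-associated traits) is surfaced as a
separate column but never merged into the ranking, since positive
presence–growth association is the hypothesis of interest. No significance
testing is attached to the distances; the method is a screen, not a test.

## Majority-rule consensus trees

Each unrooted gene tree is decomposed into non-trivial bipartitions,
canonicalized as the side not containing a fixed reference taxon (the
lexicographically smallest leaf). The consensus retains splits present in
strictly more than `threshold` (default 0.5) of the trees — a split in
exactly half is excluded, matching the strict-majority behaviour of classic
consensus programs. For thresholds ≥ 0.5 retained splits are pairwise
compatible, hence laminar once canonicalized, and assemble uniquely by
largest-first containment insertion; unresolved parts remain polytomies.
Edge labels carry integer-percent support. Branch lengths are ignored
throughout. All input trees must share one leaf set; supertree methods for
partially overlapping leaf sets are out of scope.

## Descriptive statistics

Panel averages are arithmetic means rounded half-up at integer precision
(matching how such tables are conventionally printed). Two coordinate
conventions coexist deliberately: gene length is end − start + 1 (1-based
inclusive), while an inversion span quoted from a printed coordinate pair is
end − start with the kilobase value truncated (floor), which reproduces
printed spans such as 1,181,452–1,350,961 → 169,509 bp → 169 Kb. tRNA and
IS-element counts are annotation keyword tallies, since detection tools
operate upstream of this package.

## The synthetic generator

`simulate.simulate_panel` draws, from one seeded root `SeedSequence` with
per-component substreams (so adding a component never perturbs another):

- **families**: `n_core` core families (a `paralog_frac` fraction gets a
  second copy in one random strain), `n_dispensable` dispensable families
  with per-strain Bernoulli presence at `presence_prob` (scalar, or sampled
  per family from a Beta), resampled so each is present in at least 2 and at
  most S−1 strains — the true class is dispensable by construction — and
  `n_unique_per_strain` strain-private families;
- **layout**: one contig per strain, genes consecutive with intergenic gaps
  uniform on 50–200 bp; HGT blocks inserted as contiguous runs at evenly
  spaced points, far enough apart that distinct blocks can never merge under
  the default gap rule;
- **sequences**: per-family length uniform on `gene_length_range` (default
  300–1500 bp, rounded to codons); start codon from
  {ATG 87%, GTG 9.53%, TTG 3.24%, CTG 0.08%} renormalized; remaining
  positions i.i.d. with per-position G+C probability equal to the gene's
  target (background N(58, 2), clipped; HGT blocks at 40 or 72, alternating);
  realized G+C therefore converges to the target as genes lengthen (mean
  absolute deviation < 1 point at 10 kb);
- **hits**: every within-family ordered pair, identity uniform on
  `hit_identity_range` (60–100), alignment ≥ 0.8·min length, E ≤ 1e-20;
  spurious cross-family pairs (count = `spurious_hit_rate` × the number of
  within-family pairs) with identity U(25, 45) and E U(1e-3, 1) — i.e. noise
  that a correctly implemented filter must remove;
- **phenotypes**: each trait is caused by a block of `causal_cluster_size`
  dispensable families sharing one presence pattern; a strain's growth call
  equals carriage, flipped with `pheno_flip_prob`; OD sampled from
  `od_growth_range` (0.5–1.2) or `od_nogrowth_range` (0.05–0.25), which
  straddle the 0.3 cut-off so binarization is unambiguous and label noise
  enters only through the flip probability;
- **species tree**: a random binary topology over the strains;
  `simulate_gene_trees` clones it and applies one random nearest-neighbour
  interchange per tree with probability `perturb_prob` (an NNI always changes
  the topology).

Default panel scale is 13 strains with 1300 core, 900 dispensable and 50
unique families per strain (~23,600 genes), sized like a small bacterial
taxon panel.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: sequence evolution (identities are drawn, not evolved),
codon usage beyond the start codon, genome rearrangements, assembly
artifacts, contig fragmentation, plasmids and prophages as replicons,
annotation error, and BLAST score idiosyncrasies. Recovery results (ARI 1.0,
distance-0 trait matches, exact block recovery) certify the pipeline's
correctness on data satisfying its assumptions, not its robustness to every
artifact of real genome panels.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale problems: the full-scale
clustering check uses the default 13-strain panel (~23,600 genes, ~250,000
hits, under a minute); accumulation uses 500–1000 sampled orderings, or
exhaustive enumeration up to 8 genomes; consensus checks use 165 gene trees
on 13 taxa. Every stochastic step takes an explicit seed, and the pipeline
writes a checksum manifest so end-to-end determinism is verifiable by
re-running.
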