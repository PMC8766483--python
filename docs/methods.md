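# Methods

## The interaction matrix

The central object is a binary host × phage matrix: `A_ij = 1` when phage
`j` lyses host `i` in an agar-overlay assay. Identifiers are compared by
exact string equality. The reader keeps hosts and phages with zero
interactions; dropping hosts never killed by any phage is an explicit,
separate step (`filter_to_infected_hosts`), mirroring the usual screening
workflow in which more strains are assayed than end up in the analysis set.
Summary statistics (`compute_properties`) are kept at full precision
internally; display rendering rounds connectance to 2 decimals and the
per-host/per-phage means to 1 decimal, half-up, matching the convention of
published survey tables.

## Modularity

Barber's bipartite modularity of a joint host/phage partition is

    Qb = (1/I) Σ_{i,j : g(i)=g(j)} (A_ij − k_i d_j / I)

with `k_i` row sums, `d_j` column sums and `I` total interactions.
Module detection is recursive bisection: within a candidate group, the
block of the full-matrix modularity matrix `B = A − k dᵀ/I` is split by the
signs of its leading singular vectors (hosts by the left vector, phages by
the right). Entries exactly at zero join the positive side — a
deterministic tie-break. An optional Kernighan–Lin step then refines each
bisection: repeated passes of greedy single-node relocations between the
two halves, each node moving at most once per pass, keeping the best prefix
of the move sequence when it improves the split; no cross-bisection moves.
A split is accepted only if total Qb strictly increases, so the returned
partition never falls below the single-module baseline of Qb = 0. Empty
rows or columns inside a recursion group stay with whichever half the
spectral split assigns them; they cannot change Qb.

The dense SVD per group is the right tool at the scales this package
targets (hundreds of hosts and phages); no sparse/implicit variant is
provided. On 100 random 4×4 matrices the procedure matches the exhaustive
optimum over all joint set partitions in ≥ 90 cases — the residual gap is
inherent to recursive bisection, which cannot represent every partition
reachable by global search.

The a-posteriori interaction ratio is `Qr = 2·(W/I) − 1` where `W` counts
interactions whose endpoints share a module: `Qr = 1` exactly when the
partition cuts no interaction.

## Nestedness (NODF)

For every ordered pair of rows with strictly decreasing degree
(`k_i > k_j > 0`), the paired score is the fraction of the sparser row's
interactions also present in the denser row; ties and empty rows score 0;
likewise for columns. NODF is the sum of paired scores divided by the
total number of row pairs plus column pairs, reported on [0, 1].

## The equiprobable null model

Each replicate places exactly `I` ones uniformly at random without
replacement among the `H × P` cells, preserving connectance exactly per
replicate (hypergeometric fill rather than independent Bernoulli cells —
the stricter reading of "preserving the overall matrix connectivity").
Results report the observed statistic, ensemble mean and standard
deviation (ddof = 1), the z-score, and the percentile as the percentage of
replicates ≤ observed. A degenerate ensemble (zero standard deviation)
yields no z-score and is flagged rather than raising. BiMat-style
t-scores are not reproduced; z and percentile carry the same information.

## Host-range concordance

A phage's binary kill vector `x` over the `m` hosts is normalized to
`p = x / Σx`, a probability distribution of killing. For a group of `n ≥ 2`
phages the scaled host range divergence is

    D_h = [H(mean of p vectors) − mean of H(p vectors)] / log2(n)

with Shannon entropies `H` in bits (`0·log 0 = 0`); the log2(n) normalizer
forces base-2 entropies. `D_h = 0` means identical host ranges, `D_h = 1`
pairwise disjoint ones; concordance is `1 − D_h`. Floating-point noise at
the boundaries is clipped. Phages killing no host have no `p` and are
excluded before the computation (an error if passed explicitly).

Genus-level concordance is computed in two modes: `all_members` (every
usable phage in the genus — the conservative published convention, inflated
by intra-species "blooms" of near-identical phages) and
`single_representative` (one phage per species, drawn uniformly with an
explicit seed, since no selection rule is canonical). The representative
mode is undefined at species level and rejected there.

Test choices follow the conventions of the analyses they accompany:
Welch's unequal-variance t-test (two-sided) for species- vs genus-level
concordance; equal-variance Student's t-tests for pairwise morphotype
kill-breadth comparisons; a two-sample two-sided Kolmogorov–Smirnov test
for life-history contrasts; a one-sample two-sided Wilcoxon signed-rank
test against 1 (exact null distribution for n ≤ 25) for r/m values; and
Spearman rank correlation with average-rank ties for concordance vs r/m.
The r/m composition `(R/θ)·δ·ν` is consumed from externally estimated
recombination parameters; inferring them from alignments is out of scope.

## k-mer sharing

Profiles are exact sets of canonical k-mers (lexicographic minimum of the
window and its reverse complement), default k = 25; windows containing
non-ACGT symbols are skipped. Exact sets are used rather than MinHash
sketches: a sketch large enough to capture every k-mer is lossless, so the
set intersection gives the same shared counts without approximation error.
Pair tables carry shared count, Jaccard similarity, and the Mash distance
`−(1/k)·ln(2J/(1+J))` (0 iff J = 1; +inf at J = 0, where the point estimate
is undefined). Mutual information between binary pair vectors (host
sharing vs k-mer sharing) is the plug-in estimator on the empirical 2×2
table, log2, no bias correction.

## Cross-mapping simulation

The read simulator draws, per pair, an outer distance from
Normal(insert_mean, insert_sd) truncated to [2·read_length, genome length],
places the fragment uniformly, and takes read 1 as the fragment prefix and
read 2 as the reverse complement of the suffix; substitution errors occur
per base with the configured rate (default 0.001) to a uniformly chosen
different base. Defaults (100,000 pairs, 250 bp reads, 500 ± 50 outer
distance) are the parameters representative of high-quality viral
metagenome datasets. Indels and quality-score models are deliberately
omitted — they are irrelevant to k-mer-based mapping — and FASTQ output
uses a constant quality character.

A read pseudo-maps to a reference if at least one of its canonical 31-mers
occurs in the reference index. Reference coverage is the union of full
read spans projected onto the reference around each matched 31-mer,
strand-aware and clipped at the ends. The projection — rather than
counting only the matched 31-mer intervals themselves — is what gives read
length its effect: a single matching 31-mer lets a 250 bp read claim ~250
bases of reference coverage. Counting only matched-k-mer intervals would
bound the observed/expected coverage ratio by roughly
`shared_length / (10 × read_length)`, below the 0.3 detection threshold for
any single shared segment, and would make longer reads *harder* to
falsely detect — inverting the mechanism the simulation exists to study.
Expected coverage uses the Lander–Waterman form
`1 − exp(−mapped_reads × read_length / reference_length)`; detection
requires coverage ≥ 0.1, observed/expected ≥ 0.3, and ≥ 10 mapped reads
(all inclusive). The bundled false-positive experiment uses an 8 kb
source, a 1.5 kb reference sharing one 100 bp segment, and 200 read pairs
per replicate — sized so that coverage claimed through the shared segment
straddles the thresholds between 100 bp and 250 bp reads.

## Synthetic data

`generate_matrix` sizes module blocks as equally as possible (remainder to
the first blocks), fills within/between blocks by independent Bernoulli
draws, lays blocks contiguously, then shuffles rows and columns with the
seed. The optional nested block is a square strict triangle (row `i` kills
the first `side − i` of the block's phages), so both its row and column
degrees decrease strictly and its stand-alone NODF is exactly 1; it is
labelled as a single ground-truth module. Singletons are appended as fresh
exclusive row/column pairs, each its own module.

`generate_genomes` draws one uniform-ACGT template per species (no
GC-content modelling); members copy a seeded `species_identity` fraction of
template positions and draw the rest uniformly. Planted transfers paste
verbatim segments from a donor-group genome into a recipient-group genome;
a transfer of length L guarantees ≥ L − k + 1 shared k-mers (windows
spanning segment junctions can add a few more when flanks coincide by
chance). No-flow pools are enforced by verification and regeneration with
a fresh subseed: with ≥ 4 kb uniform-random genomes the probability of a
chance shared 25-mer is ≈ n²/4²⁵ per pair, so rejection essentially never
recurs, but the check makes the zero-sharing contract unconditional.
Transfers crossing pools are rejected as contradictory configuration.

`generate_host_range_groups` gives each species a template of
`kills_per_species` hosts, sharing a `genus_overlap` fraction through a
genus core; members flip each bit with the noise rate and are redrawn
(bounded) if left with zero kills, so every generated phage is usable in
concordance analyses. A one-host universe with noise is rejected as
degenerate.

## What the synthetic fixtures do and do not show

Generated matrices have sharp planted blocks and independent noise; real
interaction matrices mix modularity with nestedness gradients, phylogenetic
correlation among rows/columns, and assay noise that is not independent
across cells. Generated genomes are uniform-random with ideal species
templates; real phage genomes have skewed composition, repeats, and
mosaicism that make k-mer collision rates higher than the uniform model
suggests. Passing tests therefore demonstrate correctness of the
statistics and detectability under controlled conditions — not that any
particular empirical dataset will show the same effect sizes.

## Problem sizes

Default test and reproduction runs use matrices up to 200×200, 100-replicate
null ensembles, 20-seed recovery sweeps, 4–5 kb genomes and 200 read pairs
per mapping replicate — sizes chosen so the planted effects are
unambiguous while the full suite completes in well under a minute, since
every statistic here concentrates quickly at these scales. All entry
points accept larger sizes and replicate counts unchanged (the published
survey scale, ~280×250 with 1000-replicate nulls, runs in minutes).
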