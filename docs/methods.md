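# Methods

This note records the models, conventions and numerical choices behind
`phagenet`, in the order the pipeline runs.

## Synthetic communities (`simulate`)

The generator emulates a database of phage genomes annotated with protein
families, with a planted cluster structure:

- **Clusters.** `n_clusters` clusters of `genomes_per_cluster` genomes.
  Every member carries all `core_families_per_cluster` core families of its
  cluster, each of `accessory_families_per_cluster` cluster-specific
  accessory families independently with `accessory_carry_prob`, and
  `background_families_per_genome` private singleton families. The defaults
  used throughout the tests and the acceptance script — 3 clusters × 10
  genomes, 20 core, 10 accessory at 0.5, 3 background — give within-cluster
  overlaps of ≥ 20 families against a universe of ~185, a regime where the
  hypergeometric edge weights are decisive for true pairs yet background
  overlap contributes nothing (background families are never shared).
- **Mosaics.** Each of `n_mosaic` extra genomes draws every core family of
  cluster *k* independently with probability `mosaic_mixture[k]` (so a 50/50
  mosaic's per-cluster core counts are Binomial(20, 0.5)), plus its own
  background families. Mosaics are labelled in the planted truth with their
  majority cluster. Note a consequence quantified below: at this community
  scale a half-and-half mosaic's overlap with one source cluster is often
  *not* statistically significant, which is biologically honest — weak
  mosaicism is exactly what a significance-thresholded network suppresses.
- **Sequences.** Each family receives a random ancestor (uniform over the
  20 standard residues, length uniform in 150–400) and each member is the
  ancestor with per-site substitutions at rate 1 − `target_identity`, each
  substitution replacing the residue by a uniformly chosen *different* one.
  This makes expectations closed-form: a member matches the ancestor at
  t per site, two members match at t² + (1−t)²/19 (0.642 at t = 0.8), and
  unrelated sequences at 1/20. Uniform composition keeps the 1/20
  background-identity analysis exact.
- **Genomes.** DNA is drawn per-base: Bernoulli(`gc`) chooses {G,C} versus
  {A,T}, then a fair coin within the class; the first `dtr_length` bases are
  copied over the end of the sequence to plant an exact direct terminal
  repeat. Copying the prefix perturbs realized GC by O(dtr/length), well
  inside the ±2-point tolerance at the scales used (208 bp in 45 kb).

What the generator does **not** emulate: gene order, codon usage, indels,
domain shuffling, unequal family sizes, database-scale family universes
(thousands of families), or HGT beyond the mosaic mixture. Passing tests
therefore demonstrate correctness of the statistics and algorithms on
communities with clean planted signal, not performance on real, noisy
annotation pipelines.

## Protein families (`families`)

Similarity evidence is either an external 12-column BLAST tabular file or
the built-in scorer. The scorer seeds candidate pairs on exact 4-mers and
requires at least 4 distinct shared 4-mers per pair: a single chance 4-mer
match between unrelated 300-residue sequences occurs with probability ≈ 0.5,
so one-hit seeding degenerates to all-vs-all alignment, while homologs at
the identities that matter here (≥ 0.65 pairwise) share dozens of seeds.
Candidates are aligned locally (see below) and the score S is converted to a
BLAST-like surrogate E-value via the Karlin–Altschul form
E = K·m·n·e^(−λS) with the gapped BLOSUM62 constants K = 0.041, λ = 0.267
and m·n the product of sequence lengths. This reproduces BLAST E-value
magnitudes closely enough for a 10⁻⁴ cutoff; it is not a replacement for
BLAST statistics in general.

Family assignment: proteins hitting a reference-mapped protein below the
cutoff adopt the reference family of their best hit (lowest E, then highest
bitscore, then lexicographic subject id — deterministic); the rest are
clustered by single linkage (connected components of the sub-threshold hit
graph), and hit-less proteins become singleton families. Single linkage is
order-independent and the minimal choice consistent with assigning families
from similarity hits. Multi-copy genes collapse to presence/absence in the
profile matrix, since the hypergeometric model needs sets, not multisets.

## Sig-score network (`signet`)

The hypergeometric upper tail is summed in log space (log-gamma binomials +
logsumexp), so p-values remain usable for family universes in the
thousands; `build_network` converts the log tail directly into
Sig = max(0, −log₁₀ p − log₁₀ T) without ever materializing p, making the
edge weight immune to floating-point underflow up to the cap
`sig_max` = 300. Arguments are canonicalized (a ≤ b) so Sig(A,B) = Sig(B,A)
*exactly*, which also makes the network invariant under genome/family
permutations bit-for-bit.

Conventions: N is the column count of the supplied profile (the analyzed
universe, not any external database); T = n(n−1)/2 over the analyzed
genomes, overridable via `n_comparisons` since a database-wide correction is
a legitimate alternative; edges require Sig strictly greater than the
threshold (default 1). All three are recorded on the graph object.

## Markov clustering (`mcl`)

From-scratch dense implementation: self-loops at each node's maximum
incident weight (damping parity effects on weighted graphs; unit loops
available), column normalization, then iterations of expansion (matrix
squaring) and inflation (elementwise power, renormalization) with pruning of
entries below 10⁻⁶ followed by renormalization — so the iterated matrix is
column-stochastic to machine precision after every step (the worst observed
deviation is recorded on the result). Convergence is a max-change below
10⁻⁸; non-convergence returns a flagged best-effort clustering.

Cluster read-off: attractors are nodes with positive diagonal mass;
attractors exchanging flow form one system; every node joins the system
receiving the largest share of its column mass (ties to the lower system
index), yielding a hard partition as required downstream. Cluster ids are
dense integers ordered by decreasing size, then smallest member label, so
labellings are reproducible across runs and platforms.

The homogeneity criterion (ICCC) used to select the inflation is the
size-weighted mean, over clusters, of the average unweighted clustering
coefficient of the cluster's induced subgraph, with clusters smaller than 3
contributing 0. The criterion is deliberately pluggable: it is a heuristic
for "clusters should look like cliques", and other cohesion scores are
defensible. Sweep ties go to the lowest inflation (coarsest equivalent
clustering).

## Membership (`membership`)

m(node, cluster) = incident Sig weight into the cluster / total incident
weight; an unweighted edge-count mode is provided since proportions "of
edges or weight" are both defensible. Self-loops never count — a genome's
self-similarity is not evidence of affiliation — and a node's own-cluster
edges are those to the *other* members of its cluster. Isolated nodes get
membership 1 in their own cluster, flagged with a warning. Wedge tables pool
entries at or below the display threshold (default 0.01) into an "other"
wedge so retained proportions still sum to 1.

## Topology (`topology`)

Clustering coefficient and betweenness are computed on the unweighted
skeleton by default, matching the common network-analyzer convention for
reporting phage networks; weighted betweenness (distance = 1/Sig) is behind
a flag. Raw betweenness counts each unordered pair once; normalization
divides by (n−1)(n−2)/2 using the whole-graph n (not per-component), also a
convention choice, documented so it can be flipped deliberately. Graphs with
fewer than 3 nodes normalize to zero.

## Comparative genomics (`compgen`)

Local alignment is Smith–Waterman scoring under BLOSUM62 with BLASTp-default
affine gaps (open 11, extend 1, i.e. a k-long gap costs 11 + k), via
Biopython's `PairwiseAligner`; of co-optimal alignments the first in the
aligner's canonical traceback order is reported, keeping results
deterministic. Identity is identities over alignment columns including gap
columns (the BLAST "pident" convention); a positives percentage is reported
alongside since "similarity" in the literature sometimes means positives.
All-negative pairs yield the empty alignment (score 0, length 0).

RBH pairing keeps (a, b) iff each is the other's best-scoring hit, ties
broken lexicographically, making the pairing one-to-one and deterministic;
per-genome-pair similarity is the unweighted mean of RBH identities (no
length weighting — the statistic the field usually quotes as "average amino
acid identity over paired ORFs"). GC content excludes ambiguity codes from
numerator and denominator and is reported to 2 decimals. DTR detection is
exact-match only — the longest L with prefix(L) = suffix(L) — because the
planted and reported quantity is a single exact repeat length; near-repeats
are out of scope.

## Problem sizes and known limitations

Tests and the acceptance script run communities of 30–31 genomes
(~185 families, ~870 proteins when sequences are emitted), 50–100 replicate
seeds for recovery rates, and a 45,403 bp genome for the genome utilities;
these sizes give unambiguous planted signal and tight runtimes while
exercising every code path. The dense MCL implementation is appropriate for
networks up to a few thousand nodes; beyond that a sparse implementation
would be needed. The built-in scorer is a convenience for self-contained
pipelines and tests — for real proteomes, feed BLAST tabular output. One
property worth restating: at the default community scale a 50/50 mosaic's
per-side overlap (~10 of 20 core families) sits almost exactly at the Sig = 1
edge threshold (Sig = 0.75 at overlap 10, 1.60 at 11), so whether the mosaic
bridges both source clusters in the thresholded network is a coin flip per
side; split membership should be asserted only where the planted overlap is
comfortably significant.
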