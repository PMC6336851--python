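# Methods

This note documents the model, its numerical choices, the synthetic-data
generator, and the known limitations of `phenonet`.

## Signatures and the rank score

Every phenotypic entity — engineered nanomaterial (ENM), drug, chemical,
disease — is reduced to a transcriptional mechanism-of-action signature
over one shared gene universe of size *n*.  Chemicals and diseases carry
directional gene sets (up- and down-regulated, disjoint, at least one
non-empty); ENMs and drugs carry a total ordering of the universe obtained
by sorting the signed score

    score(g) = logFC(g) · (−log p(g))

in decreasing order (most up-regulated first).  Choices made here:

* **Logarithm base.**  Base 10 by default.  The base is a positive scalar
  on −log p, so the induced ordering — the only thing downstream steps
  consume — is base-invariant; the test suite asserts this property on
  random tables.
* **Zero p-values** are floored to half the smallest positive p-value in
  the same table (falling back to the smallest positive normal float when
  no positive value exists).  This avoids infinite scores without
  disturbing ranks.
* **Ties** in the score are broken by gene identifier, lexicographically.
  This makes ranking deterministic across platforms and runs; no
  tie-aware Kendall variant is needed downstream because orders are
  always strict.
* Probe-level aggregation, normalization and differential-expression
  fitting are upstream concerns: the package starts at the
  (gene, logFC, p) table.

## Similarity metrics

* **Signed Jaccard (set–set).**  The plain Jaccard index is signed by
  direction agreement:
  (same-direction shared genes − opposite-direction shared genes) / union
  of all genes in either signature.  This reduces to plain Jaccard for
  up-only signatures, reaches +1 exactly for identical signatures and −1
  for direction-swapped ones.  The per-direction raw Jaccard values are
  recoverable from the sets themselves; the single combined value is what
  enters the network.
* **Normalized Kendall tau (rank–rank).**  The raw distance counts
  unordered discordant pairs (computed by merge-sort inversion counting,
  O(n log n), verified against an O(n²) pair-enumeration oracle).  It is
  mapped to [−1, 1] by 1 − 2K/K_max with K_max = n(n−1)/2, the attainable
  maximum, so identical orders give +1 and exact reversals −1.
* **Signed KS / GSEA (rank–set).**  With F_m the empirical CDF of the set
  members' rank positions and F(x) = x/n the uniform reference over
  positions, the statistic is F_m − F at the point of maximum |deviation|,
  kept signed.  Both step functions are piecewise constant on integers, so
  the deviation is evaluated at each member position and just before it;
  |deviations| are compared after rounding at 1e−12 and ties resolve to
  the earlier position, making the value deterministic.  Directional sets
  combine as (D_up − D_down)/2 (connectivity-map convention); if only one
  direction exists its statistic is used unscaled (negated for a down-only
  set), preserving the full dynamic range of single-direction signatures.

All metrics are symmetric and bounded by 1 in magnitude; these are
property-tested on random inputs.

## Network inference

* **ECDF scaling.**  The three metrics have incommensurate distributions,
  so each off-diagonal cell's weight is the empirical CDF of |similarity|
  within its *metric stratum* (all kendall cells, all jaccard cells, all
  ks cells, upper triangle).  Weights therefore lie in (0, 1], are
  monotone in |similarity| within a stratum, and each stratum's maximum
  maps to exactly 1.  Signs are copied unchanged (a raw similarity of 0
  gets sign +).  Scaling per stratum, rather than globally, is what makes
  the metrics comparable on one graph; it is the package's choice where
  the procedure was genuinely open.
* **Mutual-rank pruning.**  Each node ranks its neighbors by weight,
  descending; edge (i, j) survives at fraction th iff j is within the top
  ⌈th·deg(i)⌉ of i's list and i within the top ⌈th·deg(j)⌉ of j's.
  Neighbors tied with the boundary weight are all retained (symmetric and
  deterministic).  Pruning is monotone in th, and th = 1 is the identity.
* **Size report.**  The node count is reported together with n² "matrix
  entries" — the every-ordered-pair convention under which the published
  figure for the real integration (3,516 nodes, 12,362,256 = 3,516²
  edges) was stated — while the stored graph keeps one undirected edge
  per unordered pair and no self-loops.

## Clique mining and significance

Heterogeneous cliques (3 or 4 nodes, pairwise-distinct classes) are
enumerated exhaustively per class combination, iterating the smallest
class first and intersecting adjacency masks; correctness is guaranteed by
an exhaustive-combination oracle test up to 30 nodes, not by the pruning
heuristic.

* **Strength** is the sum of *absolute* edge weights.  Signs mark
  concordance, not strength: a strongly anti-similar edge is still a
  strong connection (a drug that counteracts a disease is mechanistically
  close to it), so discordant edges must not cancel concordant ones.  The
  signed sum is reported alongside for interpretation.
* **Null model.**  The multiset of upper-triangular off-diagonal weights
  of the complete matrix is permuted uniformly and mirrored; node labels
  and degrees are not preserved (the matrix is shuffled, not relabelled).
  Each permutation uses its own seed stream (seed, permutation index), so
  results are reproducible and independent of evaluation order.
* **P-values** use the add-one estimator
  p = (1 + #{permuted ≥ original}) / (n_perm + 1); ties count against the
  clique (comparison includes a 1e−9 relative guard so exact ties are not
  lost to float summation order).  p is therefore in (0, 1] and
  super-uniform under the null, which the test suite checks empirically.
* **FDR** is Benjamini–Hochberg (via statsmodels), applied across all
  enumerated cliques of a fit.
* **Selection** keeps cliques discovered at th ≤ 0.4, with ≥ 1 member
  pair in the known-association table, and q < 0.05.  The q-value (not
  the raw p) is compared to the 0.05 level, the coherent reading of
  "corrected … < 0.05".

## Validation layer

* **Mantel test**: Pearson r on vectorized upper triangles; the null
  jointly permutes rows and columns of the second matrix; two-sided on
  |r| by default (validation claims concern the existence of concordance;
  one-sided available).  Default 10,000 permutations, configurable.
* **Optimal string alignment** (restricted Damerau–Levenshtein) for
  structure strings, converted to similarity by 1 − d/max(len₁, len₂),
  which bounds values in [0, 1]; two empty strings count as identical.
* **Known vs unknown KS**: two-sample Kolmogorov–Smirnov (scipy) on the
  network weights of known vs unknown pairs of one class pair, with the
  shift direction logged.

## Synthetic data

The generator plants the structure the framework is designed to detect.
Each block owns a template ranking of the universe; the block's up/down
set templates are sampled from the top/bottom 15% of that ranking, so all
three similarity channels (rank–rank, set–set, rank–set) are coherent
within a block.  Entities take ρ of their sets from the template (rest
sampled outside all templates) and rankings perturbed by
round(noise · n(n−1)/2) random adjacent transpositions — adjacent swaps
because Kendall distance counts exactly such inversions, giving direct
control of the expected within-block distance.  Anti-correlated entities
get the reversed template order or swapped set templates.  Known
associations sample a coverage fraction of the planted within-block,
concordant, cross-class pairs.

Defaults are the study conditions used throughout the tests: 200 genes, 6
entities per class, 2 blocks, ρ = 0.8, noise = 0.1, 20-gene up and down
sets, no anti-correlated entities, coverage 0.5.  These are desk-scale
stand-ins for the real integration (thousands of genes and entities);
recovery results on them demonstrate that the machinery finds planted
concordance, not that it would reproduce any particular real-data
finding.  The generator does not model microarray noise distributions,
curation bias in association databases, or unbalanced class sizes.

## Problem sizes and determinism

The test and acceptance workloads use 16–30-node networks, 100–200-gene
universes, 200–500 permutations, and 50–200 replicates for stochastic
checks — sizes chosen so the full pipeline (including its brute-force
oracles) runs in seconds while leaving the statistics enough resolution
(50 replicates bound a 90% success criterion; 500 permutations give a
p-value floor of 0.002).  All randomness flows from explicit seeds through
labelled child streams (seed, stage, index), so adding a stage never
shifts another stage's draws and every run is bitwise reproducible.

## Known limitations

* The Kendall normalization assumes strict total orders; signatures with
  genuinely tied scores are disambiguated lexicographically rather than by
  a tie-aware tau.
* The weight-shuffling null ignores degree structure; hub nodes can make
  it liberal for cliques centred on them.  This matches the stated
  shuffling procedure but is a known property of matrix-shuffle nulls.
* ECDF scaling is rank-based: it discards the absolute scale of
  similarities within a stratum, so a stratum of uniformly weak
  similarities still spreads over (0, 1].
* The exhaustive clique search is quadratic-to-quartic in class sizes; it
  is meant for networks up to a few thousand nodes after pruning, not for
  dense million-edge graphs.
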