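# Methods

## Data model and normalization

The unit of analysis is a pair of family-level abundance tables (taxa ×
time-series samples) from a control and a perturbed (bioaugmented)
community, sampled on the same dates. Count tables are normalized by
rescaling every sample to the minimum library size (counts ×
min-depth/depth) and discarding taxa that fall below one adjusted read in
*every* sample — the least destructive reading of the discard rule, keeping
any taxon that clears one read somewhere. Normalization and discard run on
the merged C+B table so a taxon present under only one condition keeps its
zero row under the other; this is what makes the presence (Venn) partition
meaningful. Relative abundances are percentages summing to 100 per sample.

## Abundance features

The abundance level uses the presence-mean x̄ᵢ (sum over samples divided by
the number of *positive* samples): H strictly above 1%, R strictly below
0.1%, L on the closed band [0.1, 1] ("from 0.1 to 1%" read as inclusive).
An all-zero profile is assigned mean 0 rather than an error so
condition-specific taxa survive the pipeline. Core means positive in every
sample; nR = rare and not core. For the single per-taxon annotation table
the presence-mean is computed over the concatenated C+B samples; the
per-condition form is available through the same function.

Differential status is a two-sided paired t-test on date-aligned samples at
α = 0.05 with no multiple-testing correction (none is applied in this style
of analysis; the planted-truth tests measure sensitivity, not FDR).
Identically zero differences give p = 1 and NDiff_DN (tie broken downward,
never NaN).

Diversity indices are Shannon (natural log), inverse Simpson, and classic
Chao1 S_obs + F1²/(2F2) with the F2 = 0 fallback S_obs + F1(F1−1)/2; they
are cross-checked against scikit-bio in the test suite and serve the
baseline contrast that diversity misses what the network sees.

## Co-occurrence clusters

Correlation significance everywhere is the t transform of Pearson's r with
n − 2 degrees of freedom, two-sided, α = 0.05 (at n = 7 paired dates the
critical |r| is ≈ 0.7545; at the 14 concatenated samples ≈ 0.532).

Clustering is scipy average-linkage agglomeration under correlation
distance (1 − r) on the concatenated C+B profiles — the literal reading of
"profiles combined" — cut at 1 − r_crit(14) by default (configurable; the
original analysis does not state its cut). Inside each flat cluster, a pair
is kept only if its within-condition correlation is significant *and* at
least one member is an anchor (significant r_CᵢBᵢ); members with no kept
link are dropped, and links are tagged before/after/both by which
condition's correlation is significant. A member's epoch can be "both";
clusters need ≥ 2 members. Output ordering and labels (G1, G2, …) are
deterministic: size-descending, then first member.

Trajectory shapes are an invented, documented rule (the source analysis
names the three shapes without defining them): least-squares quadratic in
the date index; "convex" (a mid-series peak) requires a negative quadratic
coefficient, an interior vertex, and a partial F-test p < 0.05 for the
quadratic term; otherwise the linear slope's sign gives ascent/descent,
with constants degenerating to descent. The rule is invariant under
positive affine rescaling.

Feature associations use Fisher's exact test for 2×2 tables and a
Monte-Carlo Fisher test (permutation of one margin, tables ordered by their
conditional hypergeometric probability, 10⁵ permutations by default,
seeded) for larger tables, since scipy's exact test covers only 2×2.

## Ensemble gLV network inference

The forward model is the discrete-time gLV recursion
xᵢ(k+1) = xᵢ(k)·exp(Δt(bᵢ + Σⱼ aᵢⱼ xⱼ(k)) + ε). Fitting is gradient
matching: per-capita log growth regressed on (1, x₁, …, x_N) by ridge
least squares (default λ = 10⁻³, because N usually far exceeds the number
of transitions). Numerics: predictors are mean-centered (the intercept is
un-shifted afterwards), columns are norm-equilibrated, the ridge solve uses
the dual (m × m) form when transitions are fewer than taxa, and the λ = 0
path adds one round of iterative refinement. Transitions with a zero
endpoint are skipped per taxon (log undefined); a half-minimum
pseudo-abundance alternative exists but is off by default. Replicate
series (e.g. several reactors) may be passed as a list; their transitions
are pooled without crossing series boundaries.

The ensemble protocol fits 1000 networks (default), each on a random 90%
taxon subset, and records each ordered pair's coefficient sign whenever
both taxa are present and |aᵢⱼ| clears a 10⁻¹⁰ floor. Coherence is the
modal-sign fraction among runs with a signed outcome (runs missing the pair
are excluded from the denominator); an edge is reliable iff coherence
≥ 0.9 *and* a one-sided exact binomial test of the modal count against 0.5
gives p < α — the weakest defensible reading of an unspecified
"proportional test". Strength is the median |aᵢⱼ| over modal-sign runs;
direction is j → i so indegree counts incoming influences. Top-k slicing
breaks ties lexicographically by (source, target) for determinism.

## Topological niche

Centralities per strength level: indegree / (n−1), betweenness normalized
by (n−1)(n−2) (networkx Brandes), and eigenvector centrality (computed on
the reversed graph so influence flows into a taxon; reporting only — it
enters no decision rule). Taxa absent from a sub-network score 0 at that
level, and normalization keeps values comparable across sub-networks of
different size.

The niche score sums the B − C centrality differences across the strength
grid and divides by the maximum absolute sum over taxa. Read literally
(per-taxon maximum over levels in the denominator) the statistic can leave
the stated [−1, 1] range; the cross-taxon normalization is the reading that
guarantees the range, and the literal variant is available behind
`per_taxon_denominator=True`. The ±0.1 band gives four classes; the mixed
case (one score in-band, one out) is not covered by the stated rules and
conservatively maps to "none". The default grid is {500, 1000, 1500, 2000,
all}.

## Motif analysis

A labeled n-node digraph (n = 3, 4) is encoded as the integer with bit
weight 2^(n²−(n(i−1)+j)) per edge i → j; the canonical class identifier is
the minimum over all n! relabelings, precomputed for every mask by
vectorized bit permutation. Under this convention the printed names hold:
36 convergence, 6 divergence, 12 chain, 38 feed-forward, 98 cycle, 74
reciprocal dyad + in-edge, 78 reciprocal hub; exhaustive enumeration gives
exactly 13 connected 3-node and 199 connected 4-node classes.

The census counts *induced* occurrences — every weakly connected n-subset
contributes one count under its induced type — via ESU (exact subgraph
enumeration), verified against brute-force subset enumeration. The null
model is pairwise edge switching that preserves every node's in- and
out-degree and the global count of reciprocal dyads (singles swap with
singles, rejecting switches that would create a mutual pair; dyads swap
with dyads), 100·|E| attempts. Significance: z ≥ 2 and a real count ≥ 4
against 100 randomizations (the published defaults of the classic motif
detector; configurable). A degenerate null (sd = 0) yields z = 0 when the
real count equals the null mean, else an infinite, non-significant z.
Representative motifs are significant at ≥ 3 of the 4 strength levels.
The correlated-feedback fraction requires, by default, all three nodes of
an embedded 3-cycle to be correlated taxa ("any node" mode available).

## Synthetic community generator

The generator defines the study conditions: 113 taxa, 7 paired dates,
multinomial counts at depth 19,392 ± 982, an invader at a constant
~0.4% relative abundance in the perturbed condition only, 12
condition-specific rare taxa in total (5 + 7), 25 pattern-planted taxa in
three groups (9 ascent / 8 descent / 8 convex), and 20 + 13 planted
differential taxa — the shape of the motivating experiment.

Design choices that matter, with reasons:

- **Interaction regime.** Off-diagonal magnitudes are half-normal with
  scale 0.4 against self-limitation ~0.5, with each row's off-diagonal sum
  capped at 0.8·|aᵢᵢ| (diagonal dominance, the standard construction for
  stable random communities). The couplings are deliberately of the same
  order as self-regulation: a power analysis of gradient matching
  (per-coefficient t ≈ (aᵢⱼx*/b)·√(b/2)·√m) shows weaker couplings are
  statistically invisible against 5% demographic noise at realistic series
  lengths, which would make any recovery benchmark vacuous.
- **Steady-state sampling.** Each condition is burned in for 50 noiseless
  steps before the observed window, because the motivating experiment
  samples established digesters at steady state. Without burn-in, shared
  transient drift dominates the leading principal components and masks the
  condition signal.
- **Perturbation.** The perturbed condition rewires a few interaction rows
  and applies a community-wide lognormal growth-rate shift (sd 0.15),
  emulating the added strain's broad compositional footprint; this shifts
  every taxon's equilibrium slightly, which is what makes the conditions
  separate in PCA. A side effect is that some unplanted taxa become
  genuinely differential; sensitivity is therefore measured on the planted
  set only.
- **Differential planting.** Planted taxa are drawn (deterministically)
  from unplanted taxa above 0.1% mean relative abundance, and the
  multiplicative shift is sized so the mean B−C difference equals exactly
  ±3 × the within-date difference sd *including* the multinomial count
  noise term (2·100·p̄/depth on the percent scale) — an effect defined on
  the scale the test sees.
- **Pattern planting.** Templates (linear up, linear down, symmetric peak)
  span ±50% of each planted taxon's mean level, raised to a small raw
  floor so the shapes survive finite sequencing depth; the same template
  (with independent noise) is planted in both conditions so r_CᵢBᵢ is high
  by construction.

Everything is deterministic under the master seed via spawned
SeedSequences, and the truth record (model, planted sets, seeds)
round-trips through JSON.

What the generator does *not* emulate: taxonomic misassignment, chimeras,
16S copy-number bias, compositional artifacts of primer choice,
overdispersed (non-multinomial) count noise, and time-varying interaction
strengths. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to those real-data
pathologies.

## Problem sizes and runtime

The test suite runs the full pipeline at the study shape (113 taxa, 7 + 7
samples) with the ensemble scaled to 200 networks, 3-node motifs over the
{500, 1000} strength grid and 10 null randomizations — sizes chosen so the
complete end-to-end check runs in about a minute on one CPU while
exercising every stage; the 4-node machinery is exercised exhaustively at
small graph sizes where brute-force oracles are feasible. Protocol
defaults (1000 networks, 100 randomizations, sizes 3 and 4, the full
strength grid) remain the package defaults.

## Known limitations

- With few transitions and many taxa the subset ensemble's signs are
  highly stable whether or not they are correct, so coherence alone is a
  weak guarantee on under-informative data; the reliable set is then large
  and the strength ranking (top-k) carries most of the discrimination.
  This mirrors the protocol being reimplemented rather than a bug.
- The niche normalization makes scores relative within a
  dataset; they are not comparable across datasets.
- Motif significance on very sparse graphs (< 4 instances of every type)
  is vacuous by the min-count rule, by design.
- The Monte-Carlo Fisher p-value has resolution 1/(n_mc+1).
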