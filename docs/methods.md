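# Methods

This note documents the statistical procedures implemented in
`stagenet`, the assumptions behind them, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions adopted where the design was open.

## Cohort model and preprocessing

The unit of analysis is a log2-normalized expression matrix (probes ×
samples) over five ordered groups: `normal` and tumor stages `I`–`IV`.
Normalization itself (e.g. RMA from raw array files) is out of scope;
inputs are assumed already on the log2 scale.

Probes with no gene assignment, or assigned to multiple genes, are
removed; remaining probes are collapsed to genes by the per-sample
median across a gene's probes (correlation and trend analyses operate
on gene-collapsed values — done once, up front, so every module sees
the same gene matrix).

**Outlier samples.** Samples are standardized gene-wise, projected on
the first two principal components, and flagged when the robust
z-score of their distance d from the component-space centroid,
(d − median d)/(1.4826·MAD d), exceeds k (default k = 5). This is a
deterministic replacement for the common practice of visually
inspecting PCA/t-SNE plots; with k = 5 it flags essentially nothing on
homogeneous data (~97% of simulated homogeneous cohorts yield an empty
set) while catching samples shifted globally by ~10 noise SDs. The
threshold acts on a robust z-score rather than on the raw distance/MAD
ratio because the raw ratio would flag typical samples (distances have
a large median relative to their MAD), which contradicts the intended
"flag only clear outliers" behavior.

## Differential expression

Per probe, a two-sided Welch two-sample t-test on log2 values;
log2 fold-change is the difference of group means. Degenerate cases:
both groups constant and equal → p = 1; constant but different →
p is set to the smallest positive double with a warning (the effect is
unambiguous but the t statistic undefined). Multi-probe genes
aggregate p-values by geometric mean, exp(mean(log p)), and log2FC by
arithmetic mean (consistent averaging on the log scale; the
aggregation choice for fold-changes is ours, made once).

Welch's t is used rather than a moderated (empirical-Bayes) t: the
pipeline's downstream logic consumes only p-values and fold-changes,
and at the simulated group sizes (13–37) the Welch test has ample
power at the planted effect sizes. Variance moderation is a possible
extension, not a requirement.

Gene calls use **raw** p ≤ α (default 0.05) — this matches the
filtering convention the pipeline is designed around — while BH
q-values are always emitted alongside for transparency; they are never
used to filter by default. The master DEG list is the union of the
four neighboring-stage comparisons; stage-specific biomarkers are the
intersection of one stage's four comparisons against every other
group.

## Correlation networks

For each stage with n patients, the edge criterion is the exact
two-sided Pearson test at p = 0.001: r_th = t_q/√(df + t_q²) with
df = n − 2 and t_q the upper p/2 Student-t quantile. For the reference
per-stage counts (22, 13, 37, 34, 20) this gives 0.6524, 0.8010,
0.5189, 0.5392, 0.6788 (4 dp). Correlations are computed in column
blocks (default 512 genes per block) so the d × d matrix is never
materialized; d ≈ 16,000 is feasible on a workstation, tests run at
d ≤ 500. Genes with zero variance within a stage are excluded from
that stage's network only, with a logged warning.

Weighted networks carry |r|; unweighted carry 1 (identical edge sets
by construction). Stage-unique networks subtract, by unordered pair
identity, the union of all other stages' edge sets — including the
normal network — keeping the target's weights.

Key-gene subnetworks: for each key gene, PPI partners at score ≥ 0.4
are ranked by descending score (ties alphabetically) and capped at 20;
the union of key genes and retained partners, intersected with the
master list, induces the stage network's subgraph. Genes absent from a
stage's network remain as isolated nodes, so the same node set is
comparable across stages.

## Communities and cross-stage comparison

Louvain modularity maximization is implemented in-package (both
phases: local moves, then aggregation, iterated until the modularity
gain drops below `tol` = 1e-7). Determinism: the node sweep order is
shuffled by the seed; gain ties break toward the lowest community id;
the reported Q is recomputed independently from the final assignment.
Tests compare against exhaustive partition search on ≤ 10-node graphs
and against networkx's independent Louvain on fixtures, using the best
of 5 seeds where an optimum is asserted. Weighted networks use |r| in
both the gain computations and Q. Nodes isolated after thresholding
are excluded from partitions (community membership is undefined for
edgeless genes); NMI between stages is computed on the intersection of
edge-bearing node sets.

NMI uses the sum-of-entropies (Danon) normalization,
NMI = −2·Σ N_ij ln(N_ij N/(N_i N_j)) / (Σ N_i ln(N_i/N) + Σ N_j ln(N_j/N)),
which equals 1 exactly for identical partitions. Convention for
degenerate cases (ours, chosen once): if either partition has zero
entropy and the two are not identical, NMI = 0; if both are the
single-community partition they are identical, NMI = 1.

The null model preserves node count, edge count and the exact degree
multiset: attempted double-edge swaps (default 10·|E| attempts),
rejecting any swap that would create a self-loop or duplicate edge;
weights travel with the rewired edges so the weight multiset is also
preserved. The permutation test randomizes **both** networks
independently each replicate, re-detects communities, and uses the
add-one estimator p = (1 + #{null ≥ obs})/(1 + N), whose floor is
1/(N+1) — a test reporting p at the floor should be read as "smaller
than resolvable", not as an exact probability. Calibration: on
independent random 60-node networks the p-values are uniform (KS test,
200 trials × 99 permutations, asserted in the suite).

## Edge-based enrichment

With d master genes there are N = d(d−1)/2 possible edges and, for a
set with d_set master genes, m_set = d_set(d_set−1)/2 within-set
pairs. The p-value for k of the network's n edges falling inside the
set is the upper hypergeometric tail P[X ≥ k] on population N,
successes m_set, draws n (k = 0 → p = 1). d counts the **full master
list**, not just the genes present in a given stage's network — the
population of possible edges is the same for every network, which
keeps p-values comparable across stages. The tail is evaluated through
the log-space hypergeometric survival function, stable up to
N ≈ 1.3×10⁸; exactness is asserted against rational-arithmetic
enumeration on all d ≤ 8 grids. A node-level hypergeometric
over-representation test is included as a secondary utility; it is an
in-house approximation of classical ORA, not of any web tool's
modified score. Raw p ≤ 0.05 flags significance; BH q-values are
emitted alongside.

Note that for nested sets A ⊆ B with equal k, p(A) ≤ p(B) is *not* a
theorem and is not asserted; only monotonicity in k at fixed
(N, m_set, n) is.

## Trend profiles

Genes are summarized by stage medians (robust to the very unequal
group sizes), ordered normal → IV. Model profiles are integer vectors
of length 5 starting at 0 with successive steps bounded by ±c
(c = 1 → 3⁴ = 81 profiles). A diverse subset of m = 60 is selected
greedily: seed with the all-zero profile, repeatedly add the candidate
maximizing the minimum distance 1 − corr to the selected set
(constant-vs-non-constant correlation defined as 0,
constant-vs-constant as 1; ties break lexicographically). Genes are
assigned to the selected profile with maximal Pearson correlation to
their median vector — an affine-invariant criterion, so a gene's scale
and baseline do not affect its trend; zero-variance genes go to the
all-zero profile with score 0. The greedy scheme follows the standard
short-time-series profile-mining design in spirit; bit-exact
reproduction of any specific tool's 60-profile set is not claimed, and
profile-level permutation significance testing is deliberately
omitted (the pipeline reports trends, not profile p-values).

## Drug–target–PPI assembly

Targets outside the master DEG list are dropped (warned); drugs left
with no targets are retained as flagged degree-0 nodes for provenance.
Gene–gene edges require PPI score ≥ 0.9 and both endpoints retained.
Each gene node carries, per stage, its gene weight — the sum of
incident |r| in that stage's network, so isolated genes get 0 — and
its log2FC versus normal; pathway badges come from GMT membership.
Assembly is deterministic given identical inputs.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of a staged tumor microarray
cohort: per-stage sample counts 22/13/37/34/20 by default, 1–3 probes
per gene (probabilities 0.5/0.3/0.2), planted correlation blocks,
DE shifts between neighboring stages, four trend shapes
(monotone-up/down as ±(0,1,2,3,4)·effect, step-up/down as
±(0,1,1,1,1)·effect), and outlier samples.

Key generative choices:

- **Blocks** use a one-factor model per stage: a block gene's
  unit-variance signal is √ρ·f_b + √(1−ρ)·ε, giving expected
  within-block pairwise correlation exactly ρ (default ρ = 0.9,
  4 blocks × 40 genes). The same gene→block map is used in every stage
  (independent factors per stage), so stages share community structure
  while realizing different edge sets.
- **DE shifts** (default fraction 0.1 per comparison, effect 2.0 log2
  units, noise SD 0.5) are cumulative from the test stage onward, so a
  shift planted for one neighboring comparison changes only that
  comparison's group-mean difference and ground-truth DE sets stay
  exact per comparison. Signs are random per gene.
- **Probes** add a per-probe baseline offset (SD 0.25) and observation
  noise at half the biological noise SD — enough to exercise
  geometric-mean aggregation without drowning the gene signal.
- **Outliers** replicate the normal-group profile shifted globally by
  +10 noise SDs, matching the "obviously aberrant sample" scenario the
  outlier detector is meant to catch; they are labeled `normal`.
- The per-comparison DE asymmetry seen in real staged cohorts (a vastly
  larger normal-vs-I contrast than between tumor stages) is *not*
  baked into the defaults; `de_fraction` applies uniformly per
  comparison and can be varied by the user.

What passing tests on this generator demonstrate: correct thresholds
and set algebra, detection power at the stated SNRs, exact recovery of
planted blocks/trends, calibrated nulls. What they do not demonstrate:
robustness to real-array artifacts (batch effects, intensity-dependent
variance, correlated noise across probes of different genes, heavy
tails), nor anything about the biology of any particular cohort.

## Problem sizes used in the checked runs

Tests run the generator at 100–200 genes and the reference sample
counts; the permutation-calibration check uses 200 trials × 99
permutations on 60-node networks; Louvain oracles enumerate all
partitions on ≤ 10 nodes; enrichment exactness covers all d ≤ 8 grids.
`scripts/acceptance.py` runs a 200-gene, 4-block cohort end-to-end
with 200 permutation replicates for the stage I-vs-II test. These
sizes were chosen so the whole verification cycle runs in minutes on a
single core while every assertion remains at the stated statistical
strength.

## Known limitations

- No empirical-Bayes variance moderation; very small groups (< ~8
  samples) will be underpowered relative to moderated tests.
- The correlation threshold assumes bivariate normality of
  log2-expression pairs under the null; heavy-tailed real data inflate
  the edge false-positive rate.
- Louvain is a local optimizer: on large graphs the returned partition
  depends on the seed, and only ≤ 10-node graphs are verified against
  the global optimum.
- The permutation p-value floor is 1/(n_perm + 1); claims below that
  resolution require more replicates.
- GMT-based enrichment depends entirely on the user-supplied gene-set
  snapshot; no pathway database is bundled beyond test fixtures.
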