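# Methods

## Scope and model

The package implements two analysis arms plus generators.

**Signature arm.** Two-color arrays encode the hypoxia-vs-normoxia
contrast within each array (Cy5 = hypoxic, Cy3 = normoxic), so the
design is one-sample on M = log₂(R/G): per gene, the estimate is the
mean M across arrays and the null is M = 0. Assumptions: dye bias is a
smooth function of mean log-intensity A (removable by loess);
array-to-array distributional differences are technical (removable by
quantile normalization); replicated probes are exchangeable
measurements of their gene; missingness is ignorable given expression
similarity (KNN). Variance moderation follows the standard hierarchical
model s²_g ~ s₀²·F(d, d₀): the prior (d₀, s₀²) is fit by method of
moments on log s² (digamma/trigamma matching, trigamma inverted by
Newton), giving moderated t statistics with d₀ + d degrees of freedom;
d₀ = ∞ degenerates to a common variance, d₀ = 0 to the ordinary t.

**Differential-pair arm.** After control-based normalization, pairs of
genes with pooled Pearson r > 0.80 are differenced on the log₂ scale;
the signed pair matrix is split into [D⁺ | D⁻] and factorized at
rank 2 by Lee–Seung multiplicative updates on the Frobenius objective.
The split encoding matters: a pair whose log-ratio changes sign with
clinical status activates complementary columns in the two halves, and
the rank-2 factorization separates that pattern from the flat
background profile. The permutation rank-sum test then asks whether
responders concentrate at the top of the leverage-ordered sample list.

## Tunable parameters

| parameter | default | units / scale | why |
|---|---|---|---|
| loess span | 0.3 | fraction of points | follows common two-color practice; 0 robustifying iterations |
| KNN k | 10 | genes | plain mean of k nearest genes, RMS distance over co-observed columns |
| fold gates | ≥ 2.5 up, ≤ −2 down | linear, signed | inclusive boundaries; down gate means ratio ≤ 1/2 |
| FDR gate | 0.05 | — | 0.005 selectable (both conventions are in circulation for this gate) |
| correlation threshold | 0.80 | Pearson r, signed | strictly greater-than; anti-correlated pairs never qualify |
| pair universe | 26 targets + 6 housekeeping | — | `include_housekeeping=False` restricts to the 26 targets |
| NMF | k=2, 20 restarts, max 2000 iterations, tol 1e-6 | — | restart spread on 19×~16 inputs is < 0.01% relative |
| permutations | 100 000 | — | exhaustive enumeration replaces sampling when C(n, n_R) ≤ 200 000 (C(19,9) = 92 378, so the 19-sample cohort is exact) |
| background | mean of water wells, floor 1 count | counts | mean+2SD variants deliberately out of scope |
| sidedness | two-sided | — | min-tail doubling capped at 1; one-sided modes available |

## Design choices where the procedure was open

- **Leverage** is the normalized squared loading
  ℓᵢ = W[i,c]² / Σₖ W[i,k]² of a row (or H column for features) on its
  assigned cluster c = argmax loading. It is scale-invariant and lies
  in [0,1]; rows with all-zero loadings get sentinel cluster 0.
- **Composed sample ordering**: the cluster with the larger total W
  mass first, descending leverage within each block, ties broken by
  label. The rank-sum score runs over this global ordering; a
  within-cluster variant (`cluster_restricted_test`) is provided since
  "on top of a given cluster" admits both readings.
- **Reported top pair** = feature with the globally largest leverage,
  mapped back to its pair. On the synthetic stated world this rule
  identifies the planted pair far more reliably than restricting to
  the non-lead cluster (86 vs 52 of 100 seeded runs).
- **Channel quantile step** operates on reconstructed log₂
  single-channel intensities (A ± M/2) and M is recomputed, mirroring
  the stated stage order loess → channel quantile → M quantile.
- **Housekeeping aggregation** in ΔΔCt is the arithmetic mean on the
  Ct scale (geometric mean of expression); qPCR duplicates are
  averaged on the Ct scale, with a warning (not an error) when wells
  diverge by more than 1 cycle.
- **p-value estimator**: sampled permutations use the add-one estimator
  (1 + #extreme)/(B + 1), so p ≥ 1/(B+1) and p = 0 is impossible;
  exhaustive mode reports the exact tail fraction.

## The synthetic world

`simulate_nanostring_cohort` emulates a 19-patient cohort (9
responders, 10 non-responders) measured on a 32-gene codeset (26
targets, 6 housekeeping) with spiked positive-control ladders and
water wells. Latent expression is log-normal on the log₂ scale;
counts = round(2^latent · lane scale) + Poisson background, floored at
1; lane scales are log-uniform on (0.7, 1.4) and hit every well, so
normalization is a solvable inverse problem. Eight correlated pairs
are planted via shared per-sample factors; pair members draw
neighboring baselines (offset sd 0.25 log₂) because highly correlated
genes are expected to sit at similar expression levels — that is the
premise of the differential-pair construction. The first pair carries
the group effect (default 2.0 log₂ units on gene T01 in responders);
its shared-factor variance is solved in closed form so that the
*pooled* correlation equals the configured level (0.9) despite the
between-group shift, which is what the r > 0.80 gate actually sees.
Noise (0.25 sd log₂), the effect size and the correlation level are
implementer-chosen — the clinical cohort this emulates published no
such estimates — and were fixed before the recovery experiments were
run.

`simulate_microarray_panel` plants 26 up (fold 4) and 9 down (fold
1/4) genes among 400, with a sinusoidal dye bias in A, per-line
channel efficiency offsets, replicated probes for 20% of genes, and
exact counts of flagged and missing entries. `simulate_ct_table`
builds Ct = baseline − log₂(expression) + noise with a global loading
offset per condition that housekeeping normalization removes.

What a green test does **not** establish: the generators draw
independent Gaussian noise with no count overdispersion beyond
Poisson background, no correlation between technical factors and
biology, no batch structure, no probe-sequence effects and no dropout;
real cohorts are harder in all of these directions. Recovery rates
measured here (e.g. the planted pair is top-leverage with permutation
p < 0.05 in ≥ 85/100 seeded runs at effect 2.0) are therefore upper
bounds on what identical settings would achieve on real data.

## Numerical notes

- Quantile normalization with missing values interpolates each
  column's empirical quantile function onto a common grid; for
  complete equal-length columns this reduces exactly to replacing
  sorted values by row-wise means, and the operation is idempotent.
- Control-based normalization uses the cohort **arithmetic mean of
  per-lane geometric means** as reference (nSolver convention).
  Rescaling one lane is therefore undone only up to a cohort-wide
  constant (the reference moves with the lane); every within-sample
  statistic downstream — pair differences, orderings, tests — is
  unaffected, and the tests assert invariance up to that common shift.
- NMF updates add 1e-12 to denominators; the error trace is recorded
  per iteration and is non-increasing (asserted at 1e-10 slack).
  Restarts draw successive initializations from one seeded generator,
  so results are bit-reproducible for a fixed seed.
- Welch is the default two-sample t (Student selectable); the
  degenerate zero-variance/equal-means case returns p = 1.

## Known limitations

- The pair search does no multiple-testing control (by design: the
  analysis reports the single top-leverage pair).
- No amplification-efficiency correction in ΔΔCt; no background
  models for arrays; no RCC XML dialect beyond a simplified CSV.
- Rank selection for NMF is fixed at k = 2; no consensus clustering.
- With ~16 split columns from 19 samples the factorization is small
  enough that multiplicative updates converge in well under the
  iteration cap; behavior on much larger matrices is untested.
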