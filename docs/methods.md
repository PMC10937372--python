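# Methods

This note documents the statistical models implemented in `mameta`, the
assumptions behind them, the synthetic-data generator that exercises them,
and the numerical and design choices made where more than one reasonable
option existed.

## Axes of genetic variation

Studies are compared through the mean absolute difference in effect-allele
frequency over the SNVs reported by *all* studies, after aligning alleles
to the first-reporting study and excluding strand-ambiguous (A/T, C/G)
SNVs. Mean squared difference is available as an option
(`metric="mean_sq"`). The resulting distance matrix is embedded by
classical multidimensional scaling: the squared distances are
double-centred, eigendecomposed, and the leading eigenvectors (ordered by
decreasing eigenvalue, deterministic sign convention: largest-magnitude
entry positive) become the per-study axis coordinates. The coordinates
used as regression covariates are unit-norm eigenvectors; since weighted
least squares is invariant to affine rescaling of covariates, the choice
of whether to scale by the square root of the eigenvalue does not affect
any downstream test. `AxisCoordinates.embedding()` exposes the scaled
version, which reproduces pairwise distances optimally in the rank-T
sense and is what the distance-reconstruction tests check. A matrix of
all-zero distances (identical studies) raises `DegenerateAxesError`
rather than returning arbitrary axes.

## Meta-regression and heterogeneity partition

For one SNV with effects β̂_k, standard errors s_k (treated as fixed and
known — the standard summary-statistics assumption) and weights
w_k = 1/s_k², the model

  β̂_k = β₀ + Σ_t β_t x_tk (+ δ₁·BMI_controls,k + δ₂·BMI_cases,k) + ε_k

is fitted by weighted least squares. Writing RSS(M) for the weighted
residual sum of squares of model M:

* association statistic = Σ w β̂² − RSS(full), df = 1 + #covariates;
* ancestry-correlated heterogeneity = RSS(baseline) − RSS(full), df = T,
  where the baseline holds the intercept and any extra covariates (the
  BMI terms) but not the axes;
* residual heterogeneity = RSS(full), df = K − 1 − #covariates.

P values come from the chi-square distribution with the stated df.
Without extra covariates the two heterogeneity statistics sum exactly to
Cochran's Q of the intercept-only inverse-variance fit; this identity is
asserted to 1e-8 relative in the test suite. With zero axes the
meta-regression reduces exactly (not approximately) to fixed-effects
meta-analysis. SNVs reported by fewer than five studies are excluded by
default (`min_studies=5`); per-SNV degrees of freedom always reflect the
contributing-study count. Singular designs (collinear covariates,
including constant BMI columns) are flagged and the SNV skipped with a
logged reason rather than fitted unstably.

Genomic-control λ converts each P value to its 1-df chi-square quantile
and reports the median over SNVs divided by 0.4549 (the null 1-df
median), to three decimals. For the multi-df meta-regression tests this
1-df convention is a deliberate, documented choice; λ is a diagnostic,
not an inferential quantity, and the convention matters only for
comparability.

Reported thresholds (Bonferroni α/n) are rounded to two significant
figures for presentation; raw values are retained internally and used for
all decisions.

## Signals and loci

Clumping follows the standard greedy procedure: SNVs below the
genome-wide threshold (default 5×10⁻⁸) are visited in ascending P value —
ties broken by (chromosome, position, effect allele) so output is
invariant to input row order — and each unassigned SNV seeds a signal;
unassigned significant SNVs strictly within 5 Mb of the index with
max-over-panels r² > 0.05 join it. Membership distance is measured from
the index only (not updated as members join), the convention of standard
clumping tools. r² is the squared Pearson correlation of 0/1 haplotype
allele vectors (haplotype, not genotype, correlation); monomorphic SNVs
give an undefined r² in that panel and are excluded from the max. Index
SNVs under 1 Mb apart chain into loci by single linkage; locus bounds
extend 500 kb beyond the extreme indexes, floored at position 1. Novelty
uses closed-interval containment of known-variant positions.

## Sample-size-corrected z-scores and clustering

Trait associations are placed on a common scale by
Z_ij = β_ij/(√N_i · s_ij), where N_i is the phenotype's maximum sample
size, sign-aligned to the T2D risk allele; unreported or
allele-inconsistent pairs are missing. The z-scores are *not*
re-standardized per phenotype before clustering (the sample-size
correction already yields a common scale); a config switch exists for the
alternative.

Clustering is hard k-means with iterative imputation. Iteration 1 fills
each missing cell from the phenotype's observed marginal (resampling
observed values, not a parametric fit) and runs Lloyd's k-means from
k-means++ seeds; later iterations redraw missing cells from the observed
values of the same phenotype within the cell's current cluster, so
between-phenotype correlation enters through the cluster conditioning.
Imputed entries are down-weighted early: they are multiplied by
min(1, i/n_end), a penalty decaying to zero by iteration n_end (defaults
n_iter = 10, n_end = 8); the final model carries no penalty, and final
centroids are exactly the member means of the imputed matrix. Because
imputation changes the geometry between iterations, k-means is re-seeded
(10 k-means++ restarts, best inertia kept) at every iteration rather than
warm-started — warm starts were observed to lock in early local optima.
With no missing entries the procedure is bit-identical to plain
multi-restart Lloyd's k-means under the same seed. Empty clusters are
re-seeded at the farthest point, logged.

The number of clusters is chosen by majority vote over eight validity
indices — Calinski–Harabasz, silhouette, Davies–Bouldin, Dunn, C-index,
gap statistic (Tibshirani one-standard-error rule, 10 uniform reference
draws), Hartigan (≤ 10 rule) and Krzanowski–Lai — each voting by its
native rule; ties go to the smaller k. This replaces the larger
overlapping index battery sometimes used for the same purpose: several of
those indices are redundant or underspecified, and the list here is
configurable.

Cluster–phenotype profiles regress the imputed z-scores on cluster
indicators without intercept, so γ_ik is exactly the within-cluster mean;
P values are coefficient t-tests and the heatmap temperature is
sign(γ)·(−log₁₀ P). Cluster-level T2D effects use inverse-variance
weighted regression on cluster indicators, with heterogeneity tested by
the deviance difference against the grand-mean model (chi-square, k−1
df); axis z-score differences across clusters use one-way ANOVA.

## Firth enrichment

The enrichment model is logistic: Y_j = 1 for index SNVs, 0 for null SNVs
(within 50 kb of an index and r² ≤ 0.05 with it in *every* reference
panel), with intercept, three genic indicators and the cell-type peak
indicator. Fits maximize the Jeffreys-prior-penalized likelihood
ℓ(β) + ½ log det I(β) (Firth), by Newton iterations with the
hat-diagonal-adjusted score and step-halving that enforces a
non-decreasing penalized likelihood; convergence at max coefficient
change < 1e-8 or 50 iterations, with non-convergence flagged and the last
iterate returned. Estimates stay finite under complete separation.

The enrichment test is a penalized likelihood-ratio statistic on 1 df.
Crucially, the null fit constrains θ = 0 *within the full model's
penalty* (the constrained-fit construction used in Firth-regression
practice) rather than refitting a lower-dimensional model: comparing
penalized likelihoods across designs of different dimension leaves an
O(log n) penalty offset in the statistic and badly inflates type I error,
which the package's null-calibration tests would catch. Null SNVs are
pooled per cluster as the deduplicated union over that cluster's indexes;
null SNVs falling in another signal's clump are not excluded by default
(configurable). Clusters below 5 index SNVs are skipped in the scan
(small-cluster Firth estimates are unstable), logged. Intervals are
stored 0-based half-open (BED); SNV positions are 1-based; a SNV at
1-based position p overlaps [start, end) iff start ≤ p−1 < end, and the
conversion is property-tested at both boundaries.

## Partitioned polygenic scores

Variant QC retains SNVs with folded MAF ≥ 0.01, imputation r² ≥ 0.7 and
Hardy–Weinberg exact P ≥ 10⁻⁶ (boundaries inclusive); the HWE test is the
standard exact conditional test summing, over the heterozygote-count
distribution given allele counts, all outcomes no more probable than the
observed one (log-gamma arithmetic, a 1+1e-12 ratio guard against
floating-point ties).

Weights are the ancestry-specific pooled log-ORs of the risk allele from
within-ancestry fixed-effects meta-analysis. Raw cluster scores are
weighted dosage sums over the cluster's SNVs (dosages aligned to the risk
allele, missing dosages mean-imputed per SNV); the raw overall score
equals the sum of the raw cluster scores by construction, and each score
is standardized to mean 0 / variance 1 within the analysis cohort (on the
analysis subset when one is taken). Associations are GLMs — logistic for
binary outcomes, linear for age of onset — of the outcome on a cluster
component adjusted for the overall score plus covariates; the
overall-score model omits cluster terms. Under perfect separation the
logistic fit falls back to the Firth implementation, flagged. Note that
adjusting a component for the overall score makes the *other* components
informative with reversed sign (conditional on the total, a high value of
one component implies a low value of the loaded one); this is a property
of the adjusted estimand, not a miscalibration. Pooling across ancestry
groups uses DerSimonian–Laird: τ² = max(0, (Q − df)/C) with
C = Σw − Σw²/Σw from fixed-effects weights, then inverse-variance weights
1/(s² + τ²).

## Synthetic-data generator

The generator produces the study conditions all tests run under:

* **Haplotype panels.** Ancestral frequencies uniform on (0.05, 0.95);
  group frequencies Balding–Nichols (beta) around them at the group's
  F_st (defaults 0.12/0.08/0.05 for three continental groups, the order
  of magnitude of human continental divergence). LD is block-wise: within
  blocks of 10 SNVs each haplotype shares a Gaussian factor with loading
  √0.8, thresholded so marginal frequencies are exact; blocks are
  independent. This supports clumping (high within-block r²) and
  null-SNV selection (between-block r² ≈ 0) but is *not* a realistic
  human LD map — no distance decay within blocks, no recombination
  hotspots.
* **Study summaries.** 4 studies per group by default; per-study latent
  axis coordinates are group centroids on a fixed contrast layout plus
  N(0, 0.1) jitter. True effects at causal SNVs are
  b₀ + Σ_t axis_effects·x_t (+ BMI terms); observed β ~ N(b, se²) with
  se = 1/√(2f(1−f)N_eff), the binary-trait approximation consistent with
  inverse-variance weighting. Effective sample sizes are uniform on
  [10,000, 60,000] per study (the distribution is not dictated by any
  external constraint and is configurable); equal case/control counts
  give N_eff = 2n. Monomorphic draws are excluded with a logged count.
* **Z-score matrices.** Z_ij ~ N(centroid, 1) with
  missing-completely-at-random masking; MCAR is an explicit simplifying
  assumption — the real missingness mechanism of trait lookups is
  unknown. The reference centroids used in tests are sign patterns with
  ±2 entries (per-phenotype separations of 4 z-units on differing
  phenotypes), emulating opposed cardiometabolic profiles; clusters
  separated on a single phenotype are *not* recoverable at 30%
  missingness by any method, so recovery guarantees are stated for
  multi-phenotype separation.
* **Annotations.** The first cell type overlaps index SNVs with
  probability p_index = 0.5 and null SNVs with p_null = 0.1, a planted
  log fold enrichment of log 9 ≈ 2.197; other cell types use p_null for
  both. Degenerate probabilities {0, 1} are rejected.
* **Cohorts.** Dosages Binomial(2, f) at panel frequencies (no LD between
  individuals' genotypes beyond the panel frequencies), logistic outcomes
  loading configurable log-ORs on chosen standardized cluster scores, and
  a linear age-of-onset model.

Passing tests on these data demonstrate correctness of the estimators and
calibration of the tests under the generator's assumptions; they do not
demonstrate robustness to realistic LD, ascertainment, allele-frequency
spectra or informative missingness.

## Numerical choices

* Weighted least squares by explicit normal equations with a condition
  number guard (cond > 1e12 → SNV flagged as singular and skipped).
* Heterogeneity statistics floored at 0 against floating-point negatives.
* P values from `scipy.stats` survival functions; the report clamps
  underflowed P = 0 at 1e-300 before the λ computation only.
* k-means ties and reseeding are deterministic under the run seed; all
  generator streams derive from a single integer seed via named
  `SeedSequence` spawns, so outputs are byte-identical across runs.
* Bonferroni presentation rounding: `float(f"{x:.1e}")`.
* Firth step-halving limit 30; LRT statistics floored at 0.

## Known limitations

* One chromosome coordinate space by default; no X-chromosome handling.
* The gap statistic's uniform reference is drawn over the bounding box of
  the imputed matrix, which is slightly conservative for correlated
  phenotypes.
* The enrichment scan treats cell types independently; correlated peak
  sets (e.g. related cell types from one atlas) make the Bonferroni
  family conservative.
* Random-effects per-SNV models, trans-ethnic fine-mapping,
  conditional/joint secondary-signal analysis and survival models for
  clinical endpoints are out of scope.
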