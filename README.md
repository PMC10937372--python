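# mameta

**Multi-ancestry GWAS meta-regression with heterogeneity decomposition,
mechanistic clustering, open-chromatin enrichment and partitioned polygenic
scores.**

Large type 2 diabetes (T2D) meta-analyses now aggregate summary statistics
from dozens of GWASs across continental ancestry groups. Allelic effects at
associated variants are not constant across these studies: part of the
between-study heterogeneity tracks ancestry (through allele-frequency and
LD differences, or through exposures correlated with ancestry such as mean
BMI), and part is residual. `mameta` implements the analysis stack used to
dissect that structure, exercised end-to-end on synthetic data with known
truth, for statistical geneticists who want a tested, reusable
implementation of each stage:

1. **Axes of genetic variation** — studies are embedded by classical
   multidimensional scaling of pairwise mean effect-allele-frequency
   distances; the leading axes separate ancestry groups.
2. **Per-SNV meta-regression** — with per-study effects β̂_k and standard
   errors s_k, weighted least squares (w_k = 1/s_k²) of β̂_k on T axes
   x_tk partitions the evidence into three chi-square statistics:
   association allowing ancestry-correlated heterogeneity
   (Σwβ̂² − RSS_full, df = 1+T), ancestry-correlated heterogeneity
   (RSS_base − RSS_full, df = T) and residual heterogeneity
   (RSS_full, df = K−1−T). The two heterogeneity pieces sum exactly to
   Cochran's Q of the inverse-variance fit. Mean case/control BMI enter as
   extra covariates to separate BMI-driven from ancestry-driven
   heterogeneity.
3. **Signals and loci** — greedy clumping of genome-wide-significant SNVs
   (P < 5×10⁻⁸, r² > 0.05 within 5 Mb, max over reference panels), then
   single-linkage merging of index SNVs under 1 Mb into loci with 500-kb
   flanks and novelty flagging against known variants.
4. **Mechanistic clustering** — index-SNV effects on a battery of
   cardiometabolic phenotypes become sample-size-corrected z-scores
   Z_ij = β_ij/(√N_i s_ij) aligned to the T2D risk allele; hard k-means
   with iterative imputation of missing z-scores partitions SNVs into
   clusters; k is chosen by majority vote over eight cluster-validity
   indices.
5. **Cell-type enrichment** — index vs matched null SNVs (within 50 kb,
   not in LD in any group) are compared for open-chromatin peak overlap by
   Firth bias-reduced logistic regression with genic covariates
   (exon/3'UTR/5'UTR); the log fold enrichment θ is tested by a penalized
   likelihood-ratio statistic, Bonferroni-corrected per cell-type family.
6. **Partitioned polygenic scores** — index SNVs weighted by
   ancestry-specific pooled log-ORs, split by cluster, standardized, and
   tested against outcomes by GLMs (cluster components adjusted for the
   overall score), pooled across ancestry groups by DerSimonian–Laird
   random-effects meta-analysis.

A first-class synthetic-data module generates every input with the
statistical structure the models assume — Balding–Nichols allele-frequency
divergence, block-wise LD haplotype panels, effects linear in latent
ancestry axes, planted z-score clusters with missingness, planted peak
enrichment, and cohorts whose outcome risk loads on cluster scores — so
all guarantees are testable without any data download.

## Worked example

```python
from mameta.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=1, outdir="demo_run",
    simulation=dict(
        n_snvs=2000, snv_spacing=25_000,   # 2,000 SNVs over 50 Mb
        n_causal=40, base_effect=0.08,     # 40 causal variants, log-OR 0.08
        axis_effects=(0.03, 0.0),          # effect drifts along axis 1
        missing_rate=0.2,
    ),
    n_axes=2, k_clusters=3, cohort_size=3000,
    outcome_effects={"0": 0.15},           # outcome loads on cluster-0 score
)
manifest, state = run_pipeline(cfg)
print(state["report"])
```

prints

```
# mameta run report

SNVs meta-analysed: 2000 (genomic control lambda 0.993)
Signals: 39; loci: 39
Novel loci: 39/39 (100.0%)
Heterogeneity threshold (Bonferroni, 39 signals): 1.3e-03
Ancestry-correlated heterogeneity: 38/39 (97.4%), expected 0.05, one-sided binomial P = 8.32e-109
Residual heterogeneity: 0/39 (0.0%)
Clusters: k = 3 (sizes 16, 11, 12)
Enrichment tests: 12; significant: 3
  cluster 0 x celltype_enriched: theta = 2.591 (P = 4.30e-04)
  cluster 1 x celltype_enriched: theta = 2.322 (P = 6.24e-03)
  cluster all x celltype_enriched: theta = 2.369 (P = 1.31e-04)
Pooled score associations (log-OR per SD):
  0: +0.0731 (SE 0.0444, P = 9.97e-02)
  1: -0.0061 (SE 0.0389, P = 8.75e-01)
  2: -0.0670 (SE 0.0394, P = 8.94e-02)
  overall: +0.0964 (SE 0.0331, P = 3.60e-03)
```

Reading the output: 39 of the 40 planted causal variants are recovered as
independent signals; the genomic-control λ near 1 shows the null SNVs are
calibrated. Because every causal variant's effect drifts along ancestry
axis 1, almost all signals show ancestry-correlated heterogeneity at the
Bonferroni threshold (expected count under homogeneity: 0.05), while
residual heterogeneity stays at the null level. The planted enriched cell
type is detected in both clusters and overall (planted θ = log 9 ≈ 2.20).
The outcome loads on the cluster-0 score (planted 0.15 log-OR per SD), so
the overall score is strongly associated (+0.096, P = 0.004); the
cluster-0 component, tested *adjusted for the overall score*, retains the
largest positive conditional effect (+0.073) — adjustment absorbs the part
of the planted signal shared with the total score, which is exactly what
the partitioned design is meant to expose.

The same run is available from the shell:

```bash
mameta run --config configs/demo.yaml --seed 1 --outdir demo_run
```

with stage subcommands (`mameta meta`, `mameta clump`, `mameta cluster`,
`mameta enrich`, `mameta ps`, `mameta report`) running dependency-closed
subsets.

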