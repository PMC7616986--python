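# Methods

This note documents the models, parameters and numerical conventions of
`hrcmap`, and what the synthetic-data benchmarks do and do not establish.

## Bulk meta-cohort harmonization

**Probeset summarization.** For a gene measured by m probesets over n
samples, the gene value is the first principal component of the row-centered
m×n block (SVD). The component is re-anchored: its mean and SD are set to
the weighted mean of the probesets' means and SDs, with weights proportional
to the squared PC1 loadings — probesets that dominate the component dominate
the anchor (uniform weights would let a noisy minor probeset distort the
scale). The sign is flipped to agree with the probeset of largest absolute
loading, so summaries track the dominant probe rather than an arbitrary SVD
orientation. A gene whose probesets are all constant is emitted as that
constant and flagged. Sample SDs use ddof=1 throughout the package.

**Technical correction.** Per gene, one linear model with technical terms
(continuous quality metric, processing-date factor, center factor) and
clinical terms (age, gender, stage, site, MSI; missing MSI as its own
level). Only the fitted technical contributions are subtracted; dummy
columns are centered so the correction is mean-neutral. Aliased columns are
dropped via pivoted QR with a warning. Center/plate effects are treated as
fixed effects: with small group counts the point correction is identical to
a mixed-model BLUP up to shrinkage, and the contract is simpler.

**MSI imputation.** Samples are scored with the scaled-mean MSI signature
score; the score density (Gaussian KDE, Silverman bandwidth — deterministic)
is split at the minimum-density valley between its two largest modes. If the
density is unimodal the split falls back to a two-component Gaussian
mixture; below five points, to the largest-gap midpoint. Only missing labels
are filled. At the default calibration (4 score-SD mode separation) the
Bayes error is Φ(−2) ≈ 2.3%, so ≥95% imputation accuracy is the expected
regime, which the benchmark confirms (~97%).

**Standardization to the reference.** Each dataset is mapped genewise onto a
reference subsample matched on gender × age-decade × MSI × stage (age bins
are decades; the matching variables come from the harmonization design).
Sampling is without replacement within strata; a stratum missing from the
reference borrows the nearest one (dropping MSI first, then stage), and a
target stratum larger than its reference stratum samples with replacement —
both logged. Values are mapped by `x' = (x − m_t)/s_t · s_ref + m_ref` and
clamped to the per-gene [min, max] of the full reference. Truncation is
applied per dataset at standardization time; the merged cohort stores the
bounds and satisfies them exactly. The z-map is an exact fixed point under
re-standardization wherever truncation is inactive; clipped values shift
second-pass moments, so idempotence is only guaranteed away from the bounds.
The reference itself is passed through unchanged.

## Relapse screening and signatures

Each gene is standardized across the cohort and fitted in a Cox
proportional-hazards model of relapse-free survival with the **dataset as a
stratification factor** — every series keeps its own baseline hazard, the
same inferential target as a dataset-level shared frailty and more robust
with a handful of series. The screen uses a dedicated single-covariate
Newton solver for the stratified partial likelihood (Breslow ties; simulated
times are continuous so ties are rare); `lifelines` is the independent
oracle in the tests and performs the multivariate evaluation fits. Genes
enter allHR at HR > 1 and raw Wald p < 0.05 — no multiplicity correction at
this stage, matching the screening design; a BH-adjusted column is reported
for transparency.

The epithelial split uses paired t-tests of EPCAM+ against each TME
compartment on log expression across tumors. "Fold change > 1" is read
literally as a positive paired mean log-difference; the p-value carries the
evidence burden. A gene must pass all three comparisons. With ≥14 pairs a
moderated fit would give nearly identical calls; the plain paired t keeps
the contract dependency-light.

Signature scores are scaled means: genewise z-scores averaged over signature
genes and re-standardized to mean 0 / SD 1 (so Cox coefficients are per
+1 SD). Zero-variance genes are dropped with a warning. The
replicate-adjusted variant residualizes on the replicate factor, z-scores,
and subtracts the global all-gene score (a-priori centering against
systematic sample-level shifts). Kaplan–Meier groups split at the score
median by default (tertiles available); the cut is a presentation choice and
does not enter the Cox estimates.

## Single-cell mapping

QC drops cells with mitochondrial fraction > 20% (genes matching `^MT-`),
libraries < 1000 counts, genes detected outside [200, 6000], then removes
ribosomal genes (`^RP[SL]`) and samples with < 500 remaining cells; a
deep-plate preset requires > 20,000 counts instead. Normalization scales
each cell to the median library of the **pooled analysis set** and applies
log(1+x). Pooling the normalization target matters: pooled percentile
thresholds require scores on a common scale, and per-sample medians would
re-introduce sample-level score shifts. This median-library log
normalization replaces a variance-stabilizing regression-based normalization
on purpose: the downstream percentile classifier is rank-based and robust to
the swap, and the contract stays free of a specific package's model.

Diffusion imputation builds a kNN graph on the top principal components,
with the adaptive kernel `A_ij = exp(−(d_ij/σ_i)^α)`, σ_i the distance to
the ka-th neighbor (floored at machine epsilon for duplicate cells),
symmetrized and row-normalized into a Markov operator M; the output is
`Mᵗ X`. Defaults k=15, ka=5, α=2, t=3, n_pcs=20; t=0 returns the input
exactly, and every imputed value is a convex combination of observed values,
so per-gene ranges are preserved (asserted in tests). Epithelial cells are
the graph components whose median imputed EPCAM exceeds the two-mode split
of component medians (per-cell threshold when the graph is one component).

Per-cell signature scores are plain means of imputed expression over
signature genes — no rescaling, so the 75th-percentile threshold acts on the
raw score scale. Classification is pooled across all epithelial cells of the
analysis set (per-sample mode available; the per-sample 90th-percentile
convention used for reporter-intensity calls is that mode with
percentile=90), with strict inequality at the threshold: HRC = EpiHR>q ∧
Lgr5≤q, LGR5+ the converse, both = double-positive, neither = other. With
continuous scores at most 25% of cells exceed each threshold, up to one
order statistic of discreteness.

Markers: candidates detected in >10% of target cells with |log((mean+1)
ratio)| > 0.25 (natural log; log2 configurable), Wilcoxon rank-sum
two-sided, BH at 5% FDR. coreHRC: within each sample, Pearson correlation of
each gene's imputed expression with the EpiHR score across cells; genes are
averaged over the samples where they vary and the top 100 (in rank order)
form the program. Correlations are computed per sample and then averaged —
pooling cells across samples would let between-sample shifts masquerade as
correlation.

## Association and enrichment statistics

Spearman associations report exact permutation p-values for n ≤ 10
(chunked full enumeration) and asymptotic p otherwise. Mutation effects are
two-sided Wilcoxon rank-sum tests with the median difference as effect size
(exact null for small groups). Signature-gene clustering uses complete
linkage on 1 − Pearson r, cut at k = 6; the merge_top = 3 clusters with the
highest mean **intra-cluster** pairwise correlation merge into cluster 1
(singletons rank lowest; an inter-cluster criterion is available — the
notion of "most correlated clusters" is genuinely underdetermined and the
choice is recorded here).

The maxmean statistic for set S is s⁺ = mean over S of max(z, 0), s⁻
likewise for −z, taking s⁺ if s⁺ ≥ s⁻ else −s⁻. The competitive null draws
random gene sets of size |S| from the universe (exhaustive enumeration when
there are fewer subsets than requested draws); restandardization divides
(raw − null mean) by the null SD. Following the two-column convention of
competitive gene-set tests, `p` is the upper tail P(null ≥ raw) and `p_low`
the lower tail; each is calibrated at its nominal level (a
direction-selected one-sided p would double the null rate). Rotation-based
nulls were deliberately replaced by these random-set/permutation nulls;
restandardization is preserved. Preranked enrichment is the weighted
Kolmogorov–Smirnov running sum (weight exponent on |statistic|, ties broken
by gene id for a stable order), NES normalized by the mean same-sign null
ES, p the same-sign permutation tail.

CLR composition trends add pseudocount 0.5 (zeros are structural in imaging
counts), transform to centered log-ratios (rows sum to 0 to 1e−9), and fit
per population `CLR ~ log2(size) + burden` with a tumor-level random
intercept (OLS fallback for singleton tumors). Burden classes are a
deterministic function of size, so the size slope is identified from
within-class variation — the planted-decline benchmark sizes its effect
(−0.4 CLR units per log2 cells) for ~90% planned power at 60 metastases
under that collinearity.

## Synthetic study conditions

The generators are pure functions of a `SimulationConfig`; one seed is split
into fixed substreams per dataset/patient, so identical configs give
bit-identical output.

**Bulk cohort.** Four series of 450 samples (~1800 total, matching the scale
of a merged CRC cohort); gene baselines N(7, 1) on the log scale; per-series
multiplicative scale U(0.8, 1.25) and per-gene additive shifts N(0, 0.5);
1–4 probesets per gene (probabilities 0.4/0.3/0.2/0.1) with loadings
U(0.6, 1.2) and noise SD 0.3; planted technical effects from a quality
metric, a processing-date factor and a center factor. The planted prognostic
genes form two co-expressed programs (epithelial and TME, 100 genes each)
loading on per-sample program factors with loading ρ = 0.5, and the relapse
hazard is `(b/ρ)(f_epi + f_tme)` with b = `log_hr_per_sd`: each planted
gene's **marginal** per-SD log hazard ratio is then b, which is what a
per-gene screen estimates. Summing hundreds of independent per-gene effects
instead would put var(η) ≈ 8 and Cox non-collapsibility would attenuate
every marginal estimate far below its nominal value — the co-expressed-
program construction reflects how a prognostic program behaves in real
cohorts (one signature-level hazard effect, not hundreds of independent
ones). Relapse times are inverse-transform Weibull (shape 1.2) with uniform
censoring on a 10-year window; the scale is calibrated by bisection on the
realized draws so the event fraction equals 1 − censoring_rate (0.5). MSI
samples (15%) shift a 25-gene block by `4/√25` per gene, placing the score
modes ~4 SDs apart; 30% of MSI labels are withheld. KRAS-mutant samples
(40%) shift the epithelial program by 0.3.

**Sorted compartments.** 14 tumors × 4 populations; gene-by-tumor random
intercepts SD 0.5 make the design paired; epithelial prognostic genes +1
log2 unit in EPCAM+, TME prognostic genes +1 in FAP+, residual SD 0.5.

**Single cell.** 24 patients × 600 cells (600 so that samples stay above
the 500-cell QC floor after ~5% cell loss). Negative-binomial counts with
var = μ + μ²/θ, θ = 2; per-cell libraries ~5000 counts lognormal;
mitochondrial fractions Beta(2, 23) (a few percent of cells exceed the 20%
cut) and ribosomal fractions Beta(30, 170). HRC cells up-shift the 150-gene
HRC program (the 100 epithelial prognostic genes plus 50 single-cell-only
genes) by e¹; stem cells a disjoint 20-gene program and LGR5; all epithelial
types share EPCAM and a common ~30-gene epithelial program; each TME lineage
carries a canonical marker and its own ~30-gene program, so kNN-graph
components separate by lineage as the epithelial caller assumes. Per-patient
HRC fraction (among epithelial cells) and CAF fraction are coupled through a
Gaussian copula with the Pearson parameter matched to the target Spearman
(0.6). The HRC margin puts 15% mass at exactly zero and is otherwise uniform
on [0.1, 0.6]. The lower bound is a consistency requirement, fixed by
design-time arithmetic: a pooled 75th-percentile classifier flags exactly
25% of cells, so zero-HRC patients can only stay clean if the cohort-mean
HRC abundance exceeds 25% (the CAF coupling additionally down-weights
high-HRC patients, which have fewer epithelial cells); the floor puts the
cohort mean near 30%.

**What the benchmarks do not show.** The generators omit platform chemistry,
UMI saturation, doublets, ambient RNA, per-patient expression shifts beyond
library size, and any real CRC effect sizes — planted effects are
calibration knobs, not biological claims. Passing benchmarks establish that
the pipeline recovers known structure under its own model assumptions at
realistic sample sizes; they do not certify performance on real cohorts.

## Benchmark problem sizes

The recovery benchmarks use: 2000 null genes on 800 samples / 4 datasets for
screen calibration; 100+100 planted genes on 1500 samples for signature
recovery; 50 replicates of a 1500-sample cohort for hazard-ratio recovery
(26 balanced planted genes; the per-gene coefficient is chosen in closed
form so the planted score's per-SD log-HR is 0.5, and balance across both
program factors keeps the omitted-factor attenuation negligible); 20
patients for HRC-fraction recovery; 1000 independent null sets (each with
its own null statistic vector — sets sharing one vector have correlated
outcomes and a far-overdispersed empirical rate) for enrichment calibration;
and 50 replicates of 60 metastases for the CLR trend.
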