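# hrcmap

Relapse-predictive gene-signature screening and **High Relapse Cell (HRC)**
mapping for colorectal-cancer (CRC) transcriptomics.

Most CRC relapses arise from residual disease seeded by a minority tumor-cell
state. This package reimplements, as a tested pipeline, the computational
route from bulk expression cohorts to that cell state:

1. **Meta-cohort harmonization** (`hrcmap.metacohort`) — several
   probeset-level expression series are collapsed to gene level (first
   principal component of each gene's probesets, re-anchored to the weighted
   probeset mean/SD), corrected for technical covariates, completed for MSI
   status from a transcriptomic score, standardized genewise to a reference
   series via clinically matched undersampling, truncated to the reference
   range, and merged.
2. **Relapse-gene screening** (`hrcmap.screen`) — per gene, a Cox
   proportional-hazards model of relapse-free survival on standardized
   expression with a dataset-level shared effect (stratified baseline
   hazards). Genes with HR > 1 and Wald p < 0.05 form **allHR**; the subset
   upregulated in FACS-sorted EPCAM+ epithelial cells versus all three
   microenvironment compartments (FAP+, CD45+, CD31+; paired t-tests) forms
   **EpiHR**, the rest **TME-HR**. Signature scores are the scaled mean
   (genewise z-scores, averaged, re-standardized), so hazard ratios read as
   *HR per +1 SD*.
3. **Single-cell mapping** (`hrcmap.cellmap`) — QC, median-library log
   normalization, graph-diffusion imputation
   (X̂ = Mᵗ X with M a row-normalized adaptive Gaussian kernel on the kNN
   graph of the top PCs), epithelial calling from the EPCAM level of graph
   components, per-cell signature scores, and classification at the pooled
   75th percentile into HRC / LGR5+ / double-positive / other. The
   **coreHRC** program is the top-100 genes by average per-sample correlation
   with the EpiHR cell score.
4. **Association statistics** (`hrcmap.assoc`) — Spearman association of HRC
   abundance with microenvironment populations (exact permutation p at small
   n), Wilcoxon mutant-vs-wild-type score comparisons, correlation-based
   gene clustering, the restandardized **maxmean** competitive gene-set
   statistic, weighted-KS preranked enrichment, and CLR compositional trend
   models.
5. **Synthetic cohorts** (`hrcmap.synthetic`) — seeded generators with ground
   truth: a multi-dataset batch-structured bulk cohort whose Cox–Weibull
   relapse hazard is driven by planted co-expressed prognostic programs,
   paired sorted-compartment profiles, and per-patient negative-binomial
   single-cell data with an HRC state whose abundance is copula-coupled to
   CAF abundance.

The numbered drivers under `analysis/` run these stages end to end on the
synthetic cohorts; everything they compute lives in `src/hrcmap/` and is
unit-tested.

## Worked example

```python
from hrcmap.config import SimulationConfig
from hrcmap import synthetic
from hrcmap.pipeline import build_metacohort, derive_signatures

config = SimulationConfig(n_genes=300, samples_per_dataset=150,
                          n_epi_prognostic=30, n_tme_prognostic=30,
                          log_hr_per_sd=0.25, seed=3)
pms, clinical, survival, truth = synthetic.simulate_metacohort(config)
cohort, _ = build_metacohort(pms, clinical,
                             msi_sig=synthetic.msi_signature(config), seed=3)
sorted_set, _ = synthetic.simulate_sorted_populations(config)
der = derive_signatures(cohort, survival, sorted_set)
print(len(der.allhr.genes), len(der.epihr.genes))
epi_true = set(truth.epi_prognostic_genes)
print(len(set(der.epihr.genes) & epi_true) / len(der.epihr.genes))
```

prints

```
61 24
1.0
```

i.e. the screen flags 61 relapse-associated genes on this small cohort (most
of the 60 planted ones plus a few false positives at raw p < 0.05), the
sorted-compartment split retains 24 as epithelial, and every EpiHR gene is a
planted epithelial prognostic gene (precision 1.0).

Running the full-scale drivers (`python analysis/01_simulate_cohorts.py` …
`06_association_statistics.py`) on the default ~1800-sample cohort and 24
single-cell patients yields, among others: EpiHR precision/recall 1.0,
univariate EpiHR HR(+1 SD) ≈ 1.36 (p ≈ 2e-19), 18/24 patients with HRCs,
per-patient estimated-vs-true HRC-fraction Pearson ≈ 0.99, and an
HRC–CAF Spearman ρ ≈ 0.71. Summaries land in `results/`, bulky matrices in
`scratch/` (regenerable, not versioned).

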