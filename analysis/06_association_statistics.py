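#!/usr/bin/env python
"""Association and enrichment statistics around the HRC findings.

Runs, each on data simulated or derived in the previous steps:
EpiHR gene clustering by expression correlation (merging the tightest
clusters into "Cluster 1"), competitive maxmean enrichment of the derived
signatures in a replicate-adjusted expression experiment, preranked
enrichment of the coreHRC program in a marker ranking, and the CLR
compositional trend of immune populations against metastasis size.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import hrcmap.io as hio
from hrcmap.assoc import (clr_composition_trend, cluster_signature_genes,
                          maxmean_enrichment, preranked_enrichment)
from hrcmap.benchmarks import simulate_metastasis_counts

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 20260924


def main() -> None:
    values = hio.read_matrix_tsv(SCRATCH / "harmonized.tsv")
    sigs = {s.name: s for s in hio.read_gmt(RESULTS / "signatures.gmt")}
    epihr = sigs["EpiHR"]

    clusters = cluster_signature_genes(values, epihr, k=6, merge_top=3)
    clusters.merged.rename("cluster").to_csv(
        RESULTS / "epihr_gene_clusters.tsv", sep="\t", index_label="gene")

    # competitive enrichment of the signatures in per-gene cohort statistics
    screen = pd.read_csv(RESULTS / "gene_screen.tsv", sep="\t", index_col=0)
    z = np.log(screen["hr"].dropna())
    z = (z - z.mean()) / z.std(ddof=1)
    sets = {"EpiHR": epihr.genes, "TME-HR": sigs["TME-HR"].genes}
    mm = maxmean_enrichment(z, sets, n_perm=2000, seed=SEED)
    mm.to_csv(RESULTS / "maxmean_enrichment.tsv", sep="\t")

    core = hio.read_gmt(RESULTS / "corehrc.gmt")[0]
    corr = pd.read_csv(RESULTS / "gene_score_correlations.tsv", sep="\t",
                       index_col=0)["avg_correlation"]
    pr = preranked_enrichment(corr, {"coreHRC": core.genes}, weight=1.0,
                              n_perm=2000, seed=SEED)
    pr.to_csv(RESULTS / "preranked_enrichment.tsv", sep="\t")

    counts, size, burden, tumor = simulate_metastasis_counts(SEED)
    trend = clr_composition_trend(counts, size, burden, tumor)
    trend["trend"].to_csv(RESULTS / "clr_trend.tsv", sep="\t")
    trend["average_composition"].to_csv(RESULTS / "composition_by_burden.tsv",
                                        sep="\t")

    summary = {
        "cluster1_size": int((clusters.merged == 1).sum()),
        "epihr_maxmean_restandardized": float(mm.loc["EpiHR",
                                                     "restandardized"]),
        "epihr_maxmean_p": float(mm.loc["EpiHR", "p"]),
        "corehrc_nes": float(pr.loc["coreHRC", "nes"]),
        "corehrc_p": float(pr.loc["coreHRC", "p"]),
        "cd8_size_coef": float(trend["trend"].loc["CD8", "size_coef"]),
        "cd8_size_p": float(trend["trend"].loc["CD8", "size_p"]),
    }
    with open(RESULTS / "associations.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
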