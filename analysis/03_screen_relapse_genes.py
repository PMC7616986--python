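#!/usr/bin/env python
"""Screen the harmonized cohort for relapse-associated genes.

Fits one dataset-stratified Cox model per gene, collects allHR (HR>1,
p<0.05), splits it into EpiHR / TME-HR using the sorted-compartment data,
scores the cohort with each signature, and evaluates prognostic value
(univariate and joint Cox, drop-one likelihood-ratio tests, Kaplan-Meier
split at the score median).  Also tests the EpiHR score against clinical
variables and driver genotypes.  Signatures are written as GMT and the
screen/evaluation summaries to results/.
"""

import json
from pathlib import Path

import pandas as pd

import hrcmap.io as hio
from hrcmap.metacohort import HarmonizedCohort
from hrcmap.pipeline import derive_signatures
from hrcmap.screen import (SortedPopulationSet, associate_clinical,
                           evaluate_signature_survival)
from hrcmap.scoring import score_signature
from hrcmap.assoc import associate_mutations
from hrcmap.synthetic import GroundTruth  # noqa: F401  (truth JSON fields)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    values = hio.read_matrix_tsv(SCRATCH / "harmonized.tsv")
    clinical = pd.read_csv(SCRATCH / "clinical_completed.tsv", sep="\t",
                           index_col=0)
    survival = pd.read_csv(SCRATCH / "synthetic" / "survival.tsv", sep="\t",
                           index_col=0)
    bounds = pd.DataFrame({"min": values.min(axis=1),
                           "max": values.max(axis=1)})
    cohort = HarmonizedCohort(values=values, clinical=clinical,
                              reference_dataset_id="DS1", gene_bounds=bounds)

    long = pd.read_csv(SCRATCH / "synthetic" / "sorted_populations.tsv",
                       sep="\t")
    wide = long.pivot(index="gene", columns="sample", values="value")
    meta = long.drop_duplicates("sample").set_index("sample")
    sorted_set = SortedPopulationSet(values=wide,
                                     population=meta["population"],
                                     tumor_id=meta["tumor_id"])

    der = derive_signatures(cohort, survival, sorted_set)
    der.screen.to_csv(RESULTS / "gene_screen.tsv", sep="\t",
                      float_format="%.5g")
    hio.write_gmt([der.allhr, der.epihr, der.tmehr],
                  RESULTS / "signatures.gmt")

    scores = {name: score_signature(cohort.values, sig)
              for name, sig in (("EpiHR", der.epihr), ("TME-HR", der.tmehr))}
    ev = evaluate_signature_survival(scores, survival, clinical)
    truth = json.load(open(SCRATCH / "synthetic" / "ground_truth_bulk.json"))
    planted_epi = set(truth["epi_prognostic_genes"])
    planted_tme = set(truth["tme_prognostic_genes"])
    epihr = set(der.epihr.genes)

    clin_assoc = associate_clinical(scores["EpiHR"], clinical)
    clin_assoc.to_csv(RESULTS / "epihr_clinical_association.tsv", sep="\t",
                      index=False)
    geno = pd.DataFrame(truth["genotypes"])
    mut = associate_mutations(scores["EpiHR"].scores, geno)
    mut.to_csv(RESULTS / "epihr_mutation_association.tsv", sep="\t")

    summary = {
        "n_genes_screened": int(der.screen["p"].notna().sum()),
        "allhr_size": len(der.allhr.genes),
        "epihr_size": len(der.epihr.genes),
        "tmehr_size": len(der.tmehr.genes),
        "allhr_sensitivity": len(set(der.allhr.genes)
                                 & (planted_epi | planted_tme))
        / len(planted_epi | planted_tme),
        "epihr_precision": len(epihr & planted_epi) / len(epihr),
        "epihr_recall": len(epihr & planted_epi) / len(planted_epi),
        "univariate": {k: {c: float(v[c]) for c in ("hr", "ci_low",
                                                    "ci_high", "p")}
                       for k, v in ev.univariate.iterrows()},
        "lrt_p": {k: float(v["p"]) for k, v in ev.lrt.iterrows()},
        "km_logrank_p": {k: ev.km[k]["logrank_p"] for k in ev.km},
        "kras_median_difference": float(
            mut.loc["KRAS", "median_difference"]) if "KRAS" in mut.index
        else None,
        "kras_p": float(mut.loc["KRAS", "p"]) if "KRAS" in mut.index else None,
    }
    with open(RESULTS / "screen_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
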