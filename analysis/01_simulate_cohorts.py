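#!/usr/bin/env python
"""Generate the synthetic study cohorts with ground truth.

Simulates (i) a four-series bulk meta-cohort (~1800 samples) with relapse
survival driven by two planted co-expressed prognostic programs, (ii) the
14-tumor FACS-sorted compartment set, and (iii) 24 patients of 10X-style
single-cell data with a planted High Relapse Cell (HRC) state coupled to
CAF abundance.  Full matrices go to scratch/synthetic/ (large, regenerable);
a summary of what was planted goes to results/.
"""

import json
from pathlib import Path

import hrcmap.io as hio
from hrcmap.config import SimulationConfig
from hrcmap import synthetic

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"
SEED = 20260924


def main() -> None:
    config = SimulationConfig(seed=SEED)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    pms, clinical, survival, truth = synthetic.simulate_metacohort(config)
    for pm in pms:
        d = SCRATCH / pm.dataset_id
        d.mkdir(exist_ok=True)
        hio.write_matrix_tsv(pm.values, d / "probesets.tsv", "probeset")
        pm.probeset_to_gene.rename("gene").to_csv(d / "probeset_map.tsv",
                                                  sep="\t",
                                                  index_label="probeset")
        pm.technical.to_csv(d / "technical.tsv", sep="\t",
                            index_label="sample")
    clinical.to_csv(SCRATCH / "clinical.tsv", sep="\t", index_label="sample")
    survival.to_csv(SCRATCH / "survival.tsv", sep="\t", index_label="sample")

    sorted_set, _ = synthetic.simulate_sorted_populations(config)
    long = sorted_set.values.stack().rename("value").reset_index()
    long.columns = ["gene", "sample", "value"]
    long["tumor_id"] = sorted_set.tumor_id.loc[long["sample"]].to_numpy()
    long["population"] = sorted_set.population.loc[long["sample"]].to_numpy()
    long.to_csv(SCRATCH / "sorted_populations.tsv", sep="\t", index=False)

    adatas, sc_truth = synthetic.simulate_scrna(config)
    for adata in adatas:
        hio.write_sc_sample(adata, SCRATCH / "sc" / adata.obs["patient"][0])
    hio.write_ground_truth(truth, SCRATCH / "ground_truth_bulk.json")
    hio.write_ground_truth(sc_truth, SCRATCH / "ground_truth_sc.json")

    summary = {
        "seed": SEED,
        "n_samples_bulk": int(clinical.shape[0]),
        "n_datasets": config.n_datasets,
        "n_genes": config.n_genes,
        "event_fraction": float(survival["event"].mean()),
        "n_epi_prognostic": config.n_epi_prognostic,
        "n_tme_prognostic": config.n_tme_prognostic,
        "n_sorted_tumors": config.n_tumors_sorted,
        "n_patients_sc": config.n_patients_sc,
        "cells_per_patient": config.cells_per_patient,
        "n_hrc_program": config.n_hrc_program,
        "true_hrc_fraction_range": [
            float(sc_truth.true_hrc_fraction.min()),
            float(sc_truth.true_hrc_fraction.max())],
        "n_zero_hrc_patients": int((sc_truth.true_hrc_fraction == 0).sum()),
    }
    with open(RESULTS / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
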