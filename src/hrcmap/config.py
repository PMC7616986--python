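"""Simulation configuration for the synthetic study cohorts.

A single :class:`SimulationConfig` parameterizes all three synthetic data
layers — the multi-dataset bulk meta-cohort with relapse survival, the
FACS-sorted compartment profiles, and the patient single-cell data with a
planted High Relapse Cell (HRC) subpopulation. One global seed drives
everything; per-dataset / per-patient substreams are derived from it
deterministically, so an identical config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

CELL_TYPES = (
    "HRC",
    "LGR5_stem",
    "proliferative",
    "differentiated",
    "CAF",
    "endothelial",
    "myeloid",
    "Tcell",
)

EPITHELIAL_TYPES = ("HRC", "LGR5_stem", "proliferative", "differentiated")
TME_TYPES = ("CAF", "endothelial", "myeloid", "Tcell")


def _default_props() -> Dict[str, float]:
    return {
        "HRC": 0.08,
        "LGR5_stem": 0.12,
        "proliferative": 0.15,
        "differentiated": 0.25,
        "CAF": 0.12,
        "endothelial": 0.08,
        "myeloid": 0.10,
        "Tcell": 0.10,
    }


def _default_mutation_rates() -> Dict[str, float]:
    return {"KRAS": 0.40, "TP53": 0.55, "APC": 0.70, "BRAF": 0.10}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic CRC study.

    Bulk meta-cohort
    ----------------
    n_datasets:
        Number of expression series; the first one acts as the reference
        (largest cohort) for harmonization.
    samples_per_dataset:
        Samples in each series (the default 4 x 450 mimics a ~1800-patient
        meta-cohort).
    n_genes:
        Genes in the simulated universe (planted program genes included).
    probesets_per_gene_probs:
        Probabilities of a gene being measured by 1..4 probesets.
    n_epi_prognostic / n_tme_prognostic:
        Planted relapse-associated genes expressed by the epithelium /
        microenvironment respectively.
    log_hr_per_sd:
        Per-SD log hazard ratio contributed by each planted prognostic gene.
    weibull_shape / weibull_scale:
        Baseline relapse-hazard Weibull; scale=None calibrates it to hit
        ``censoring_rate`` under uniform censoring on the follow-up window.
    censoring_rate:
        Target fraction of censored samples.
    followup_years:
        Administrative follow-up window (uniform censoring support).
    batch_shift_sd / batch_scale_range:
        Per-dataset, per-gene additive shifts and dataset-wide multiplicative
        scales creating cross-platform batch structure.
    probeset_noise_sd / probeset_loading_range:
        Probe-level measurement model: each probeset is loading * gene signal
        + independent noise.
    msi_fraction / msi_separation_sd / n_msi_genes / msi_missing_rate:
        Microsatellite-instability layer: fraction of MSI samples, the gap
        between the MSI/MSS signature-score modes in score-SD units, the
        size of the MSI gene block, and the fraction of samples whose MSI
        label is withheld (to exercise imputation).
    tech_quality_effect / tech_batch_effect:
        Planted technical effects (continuous quality metric, processing-date
        factor) that the correction step must remove.

    Single cell
    -----------
    n_patients_sc / cells_per_patient:
        Patients and target cells per patient.
    celltype_base_props:
        Baseline composition over the eight simulated cell types (sums to 1).
    hrc_caf_coupling:
        Target Spearman correlation between per-patient HRC fraction (among
        epithelial cells) and CAF fraction; induced via a Gaussian copula.
    hrc_zero_patient_rate:
        Probability mass of the copula mapped to a true HRC fraction of 0.
    hrc_fraction_max:
        Upper end of the per-patient true HRC fraction.
    hrc_effect_log:
        Natural-log up-shift of HRC-program gene means in HRC cells.
    n_hrc_program:
        Size of the HRC transcriptional program; the epithelial prognostic
        genes form its first part, the remainder are single-cell-only.
    nb_dispersion:
        Negative-binomial dispersion theta (var = mu + mu^2/theta).

    Genotypes
    ---------
    mutation_rates:
        Per-driver mutation frequencies for bulk samples.
    kras_effect:
        Latent-scale up-shift of epithelial prognostic genes in KRAS-mutant
        samples.
    """

    # bulk cohort
    n_datasets: int = 4
    samples_per_dataset: int = 450
    n_genes: int = 1000
    probesets_per_gene_probs: Tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    n_epi_prognostic: int = 100
    n_tme_prognostic: int = 100
    log_hr_per_sd: float = 0.2
    planted_gene_loading: float = 0.5
    weibull_shape: float = 1.2
    weibull_scale: float | None = None
    censoring_rate: float = 0.5
    followup_years: float = 10.0
    batch_shift_sd: float = 0.5
    batch_scale_range: Tuple[float, float] = (0.8, 1.25)
    probeset_noise_sd: float = 0.3
    probeset_loading_range: Tuple[float, float] = (0.6, 1.2)
    msi_fraction: float = 0.15
    msi_separation_sd: float = 4.0
    n_msi_genes: int = 25
    msi_missing_rate: float = 0.3
    tech_quality_effect: float = 0.3
    tech_batch_effect: float = 0.2

    # sorted compartments
    n_tumors_sorted: int = 14
    sorted_epi_shift: float = 1.0  # log2 units in EPCAM+ for epithelial genes
    sorted_tme_shift: float = 1.0  # log2 units in FAP+ for TME genes
    sorted_noise_sd: float = 0.5
    sorted_tumor_sd: float = 0.5

    # single cell
    n_patients_sc: int = 24
    cells_per_patient: int = 600
    celltype_base_props: Dict[str, float] = field(default_factory=_default_props)
    hrc_caf_coupling: float = 0.6
    hrc_zero_patient_rate: float = 0.15
    hrc_fraction_min: float = 0.1
    hrc_fraction_max: float = 0.6
    hrc_effect_log: float = 1.0
    n_hrc_program: int = 150
    n_stem_program: int = 20
    nb_dispersion: float = 2.0
    mean_counts_per_cell: float = 5000.0

    # genotypes
    mutation_rates: Dict[str, float] = field(default_factory=_default_mutation_rates)
    kras_effect: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_datasets": self.n_datasets,
            "samples_per_dataset": self.samples_per_dataset,
            "n_genes": self.n_genes,
            "n_epi_prognostic": self.n_epi_prognostic,
            "n_tme_prognostic": self.n_tme_prognostic,
            "n_hrc_program": self.n_hrc_program,
            "n_patients_sc": self.n_patients_sc,
            "cells_per_patient": self.cells_per_patient,
            "n_tumors_sorted": self.n_tumors_sorted,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("censoring_rate", "msi_fraction", "msi_missing_rate",
                     "hrc_zero_patient_rate", "hrc_fraction_min",
                     "hrc_fraction_max"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.planted_gene_loading <= 1.0:
            raise ValueError("planted_gene_loading must lie in (0, 1]")
        if not -1.0 < self.hrc_caf_coupling < 1.0:
            raise ValueError(
                f"hrc_caf_coupling must lie in (-1, 1), got {self.hrc_caf_coupling}"
            )
        props = self.celltype_base_props
        if set(props) != set(CELL_TYPES):
            raise ValueError(f"celltype_base_props must cover exactly {CELL_TYPES}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"celltype_base_props must sum to 1, got {total}")
        if any(p < 0 for p in props.values()):
            raise ValueError("celltype_base_props must be non-negative")
        n_planted = (self.n_epi_prognostic + self.n_tme_prognostic
                     + self.n_msi_genes)
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted gene sets ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        if self.n_hrc_program < self.n_epi_prognostic:
            raise ValueError("n_hrc_program must be >= n_epi_prognostic "
                             "(the program contains the epithelial prognostic genes)")
        if abs(sum(self.probesets_per_gene_probs) - 1.0) > 1e-8:
            raise ValueError("probesets_per_gene_probs must sum to 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
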