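"""End-to-end drivers gluing the pipeline stages together.

These are the functions the numbered analysis scripts, the test suite and
the acceptance benchmarks call: harmonize a list of probeset-level
datasets into a cohort, derive the relapse signatures, and map signatures
onto per-patient single-cell data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd

from . import cellmap
from .cellmap import (CellClassLabels, QCThresholds, SmoothedCellMatrix,
                      classify_cells, composition, diffusion_impute,
                      identify_epithelial, preprocess_cells, score_cells)
from .metacohort import (GeneMatrix, HarmonizedCohort, ProbesetMatrix,
                         correct_technical, impute_msi, merge_cohort,
                         standardize_to_reference, summarize_probesets)
from .scoring import GeneSignature, SignatureScores, score_signature
from .screen import (SortedPopulationSet, allhr_signature, screen_relapse_genes,
                     split_epithelial)

logger = logging.getLogger("hrcmap")


def build_metacohort(pms: Sequence[ProbesetMatrix], clinical: pd.DataFrame,
                     msi_sig: Optional[GeneSignature] = None,
                     reference_id: Optional[str] = None,
                     seed: int = 0) -> Tuple[HarmonizedCohort, Dict]:
    """Summarize, correct, impute MSI, standardize and merge the datasets.

    Returns the harmonized cohort and an info dict carrying the
    pre-standardization gene matrices and the completed clinical table
    (useful for before/after harmonization diagnostics).
    """
    reference_id = reference_id or pms[0].dataset_id
    corrected: List[GeneMatrix] = []
    clin_parts: List[pd.DataFrame] = []
    for pm in pms:
        cl = clinical.loc[pm.values.columns]
        gm = summarize_probesets(pm)
        gm = correct_technical(gm, pm.technical, cl)
        if msi_sig is not None and cl["msi"].isna().any():
            cl = impute_msi(gm, msi_sig, cl)
        corrected.append(gm)
        clin_parts.append(cl)

    ref = next(gm for gm in corrected if gm.dataset_id == reference_id)
    ref_cl = clin_parts[[gm.dataset_id for gm in corrected].index(reference_id)]
    standardized = []
    for gm, cl in zip(corrected, clin_parts):
        if gm.dataset_id == reference_id:
            # the reference is its own anchor: exact pass-through
            standardized.append(gm)
        else:
            standardized.append(standardize_to_reference(gm, ref, cl, ref_cl,
                                                         seed=seed))
    cohort = merge_cohort(standardized, clin_parts, reference_id)
    info = {"pre_standardization": corrected,
            "clinical_completed": pd.concat(clin_parts)}
    return cohort, info


@dataclass
class SignatureDerivation:
    screen: pd.DataFrame
    allhr: GeneSignature
    epihr: GeneSignature
    tmehr: GeneSignature
    split_detail: pd.DataFrame


def derive_signatures(cohort: HarmonizedCohort, surv: pd.DataFrame,
                      sorted_set: SortedPopulationSet,
                      alpha: float = 0.05) -> SignatureDerivation:
    """Cox screen -> allHR -> epithelial split -> (EpiHR, TME-HR)."""
    screen = screen_relapse_genes(cohort, surv, alpha=alpha)
    allhr = allhr_signature(screen)
    epihr, tmehr, detail = split_epithelial(allhr, sorted_set, alpha=alpha)
    return SignatureDerivation(screen=screen, allhr=allhr, epihr=epihr,
                               tmehr=tmehr, split_detail=detail)


@dataclass
class SingleCellMapping:
    """Per-patient single-cell processing artifacts and pooled calls."""

    smoothed: Dict[str, SmoothedCellMatrix]
    epithelial_mask: Dict[str, pd.Series]
    epihr_scores: pd.Series          # pooled over epithelial cells
    lgr5_scores: pd.Series
    labels: CellClassLabels
    fractions: pd.DataFrame          # per patient, among epithelial cells
    kruskal: Optional[dict] = None
    normalized: Dict[str, pd.DataFrame] = field(default_factory=dict)
    cell_patient: Optional[pd.Series] = None


def map_single_cells(adatas: Sequence[ad.AnnData], epihr_sig: GeneSignature,
                     lgr5_sig: GeneSignature,
                     qc: Optional[QCThresholds] = None,
                     percentile: float = 75.0,
                     stages: Optional[pd.Series] = None,
                     keep_normalized: bool = False,
                     **diffusion_kwargs) -> SingleCellMapping:
    """QC, impute, call epithelium, score and classify cells per patient.

    Each sample is processed independently (QC, diffusion imputation on its
    own graph, epithelial-component calling); signature thresholds are the
    pooled percentile over all epithelial cells of the analysis set.
    """
    smoothed: Dict[str, SmoothedCellMatrix] = {}
    masks: Dict[str, pd.Series] = {}
    normalized: Dict[str, pd.DataFrame] = {}
    epihr_parts, lgr5_parts, patient_parts = [], [], []
    # pass 1: QC only, so all samples can share one normalization target
    cleaned = []
    for adata in adatas:
        pid = str(adata.obs["sample"].iloc[0]) if "sample" in adata.obs \
            else "sample"
        try:
            clean = preprocess_cells(adata, qc, normalize=False)
        except ValueError as err:
            logger.warning("map_single_cells: sample %s dropped (%s)", pid, err)
            continue
        if clean.n_obs:
            cleaned.append((pid, clean))
    if not cleaned:
        raise ValueError("no sample survived QC")
    libs = np.concatenate([np.asarray(c.layers["counts"].sum(axis=1)).ravel()
                           for _, c in cleaned])
    pooled_median = float(np.median(libs[libs > 0]))

    for pid, clean in cleaned:
        cellmap.normalize_cells(clean, pooled_median)
        sm = diffusion_impute(clean, **diffusion_kwargs)
        mask = identify_epithelial(sm)
        if mask.sum() < 10:
            logger.warning("map_single_cells: sample %s has <10 epithelial "
                           "cells; skipped from scoring", pid)
            continue
        epi_sm = SmoothedCellMatrix(values=sm.values.loc[mask],
                                    params=sm.params, kernel=sm.kernel)
        smoothed[pid] = epi_sm
        masks[pid] = mask
        if keep_normalized:
            import scipy.sparse as sp
            X = clean.X.toarray() if sp.issparse(clean.X) else np.asarray(clean.X)
            normalized[pid] = pd.DataFrame(X, index=clean.obs_names,
                                           columns=clean.var_names).loc[mask]
        epihr_parts.append(score_cells(epi_sm, epihr_sig))
        lgr5_parts.append(score_cells(epi_sm, lgr5_sig))
        patient_parts.append(pd.Series(pid, index=epi_sm.values.index))
    if not epihr_parts:
        raise ValueError("no sample survived QC/epithelial calling")

    epihr_scores = pd.concat(epihr_parts)
    lgr5_scores = pd.concat(lgr5_parts)
    patients = pd.concat(patient_parts)
    labels = classify_cells(epihr_scores, lgr5_scores, percentile=percentile)
    fractions, kw = composition(labels, patients, stages)
    return SingleCellMapping(smoothed=smoothed, epithelial_mask=masks,
                             epihr_scores=epihr_scores, lgr5_scores=lgr5_scores,
                             labels=labels, fractions=fractions, kruskal=kw,
                             normalized=normalized, cell_patient=patients)


def core_program(mapping: SingleCellMapping, epihr_sig: GeneSignature,
                 k: int = 100) -> Tuple[GeneSignature, pd.Series]:
    """coreHRC: correlation-ranked genes against the EpiHR cell score."""
    samples = list(mapping.smoothed)
    smoothed = [mapping.smoothed[s] for s in samples]
    scores = [score_cells(mapping.smoothed[s], epihr_sig) for s in samples]
    avg = cellmap.signature_gene_correlations(smoothed, scores)
    core = cellmap.derive_core_signature(avg, k=k)
    return core, avg
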