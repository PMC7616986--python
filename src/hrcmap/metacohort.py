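"""Harmonization of multi-dataset expression cohorts.

Several probeset-level expression series (microarray-style) are merged into
one analysis-ready gene x sample cohort:

1. :func:`summarize_probesets` — per gene, the first principal component of
   its probesets, re-anchored to the probesets' weighted mean/SD and
   sign-matched to the dominant probeset.
2. :func:`correct_technical` — per-gene linear correction for technical
   covariates (quality metric, processing batch, center) while retaining
   clinical effects.
3. :func:`impute_msi` — missing microsatellite-instability labels filled by
   splitting a transcriptomic MSI score at the density valley between its
   two modes.
4. :func:`standardize_to_reference` — genewise standardization of each
   dataset against a clinically matched undersample of the reference
   series, with truncation to the reference range.
5. :func:`merge_cohort` — column concatenation over the shared gene set.

Clinical tables are plain DataFrames indexed by sample id with columns
``gender, age, stage, site, msi, dataset_id`` (stage in I..IV; msi in
{MSI, MSS} or NaN when unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg

from ._utils import bimodal_threshold
from .scoring import GeneSignature, score_signature

logger = logging.getLogger("hrcmap")

CLINICAL_COLUMNS = ("gender", "age", "stage", "site", "msi", "dataset_id")
STAGES = ("I", "II", "III", "IV")


@dataclass
class ProbesetMatrix:
    """Probeset x sample log-expression with technical annotations."""

    values: pd.DataFrame
    probeset_to_gene: pd.Series  # index: probeset id -> gene id
    dataset_id: str
    technical: pd.DataFrame  # per-sample: quality, scan_batch, center

    def __post_init__(self) -> None:
        missing = self.values.index.difference(self.probeset_to_gene.index)
        if len(missing):
            raise ValueError(f"probesets without gene mapping: {list(missing)[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")


@dataclass
class GeneMatrix:
    """Gene x sample log-expression with transformation provenance."""

    values: pd.DataFrame
    dataset_id: str
    provenance: List[str] = field(default_factory=list)
    flags: Dict[str, str] = field(default_factory=dict)

    def copy_with(self, values: pd.DataFrame, step: str) -> "GeneMatrix":
        return GeneMatrix(values=values, dataset_id=self.dataset_id,
                          provenance=self.provenance + [step],
                          flags=dict(self.flags))


@dataclass
class HarmonizedCohort:
    """Merged gene x sample matrix with clinical and truncation metadata."""

    values: pd.DataFrame
    clinical: pd.DataFrame
    reference_dataset_id: str
    gene_bounds: pd.DataFrame  # columns: min, max (from the reference)


def summarize_probesets(pm: ProbesetMatrix) -> GeneMatrix:
    """Collapse probesets to one value per gene via the first PC.

    The component is centered, rescaled so its mean/SD equal the weighted
    mean of the probesets' means/SDs (weights proportional to squared PC1
    loadings), and its sign is flipped to agree with the probeset carrying
    the largest absolute loading.  A gene whose probesets are all constant
    is emitted as that constant and flagged.
    """
    X = pm.values
    if X.shape[1] < 3:
        raise ValueError("summarize_probesets needs >=3 samples")
    groups = pm.probeset_to_gene.loc[X.index].groupby(pm.probeset_to_gene).groups
    flags: Dict[str, str] = {}
    rows = {}
    arr = X.to_numpy()
    pos = {p: i for i, p in enumerate(X.index)}
    for gene in groups:
        idx = [pos[p] for p in groups[gene]]
        sub = arr[idx]
        if len(idx) == 1:
            rows[gene] = sub[0]
            continue
        means = sub.mean(axis=1)
        sds = sub.std(axis=1, ddof=1)
        if np.all(sds == 0):
            flags[gene] = "all probesets constant; emitted constant value"
            rows[gene] = np.full(X.shape[1], means.mean())
            continue
        Xc = sub - means[:, None]
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = u[:, 0]
        score = s[0] * vt[0]
        j = int(np.argmax(np.abs(loadings)))
        if loadings[j] < 0:
            loadings = -loadings
            score = -score
        w = loadings ** 2
        w = w / w.sum()
        target_mean = float(w @ means)
        target_sd = float(w @ sds)
        ssd = score.std(ddof=1)
        rows[gene] = (score / ssd) * target_sd + target_mean if ssd > 0 \
            else np.full(X.shape[1], target_mean)
    if flags:
        logger.warning("summarize_probesets(%s): %d constant genes flagged",
                       pm.dataset_id, len(flags))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=X.columns)
    values = values.sort_index()
    return GeneMatrix(values=values, dataset_id=pm.dataset_id,
                      provenance=["summarize_probesets(pc1,weighted-anchor)"],
                      flags=flags)


def _design_columns(technical: pd.DataFrame,
                    clinical: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Build a centered design matrix; returns (X, tech_mask, names)."""
    cols: List[np.ndarray] = []
    names: List[str] = []
    tech: List[bool] = []

    def add(series: pd.Series, name: str, is_tech: bool) -> None:
        if series.dtype.kind in "fi":
            v = series.to_numpy(dtype=float)
            if np.ptp(v) == 0:
                return
            cols.append(v - v.mean())
            names.append(name)
            tech.append(is_tech)
        else:
            s = series.astype("object").where(series.notna(), "missing")
            levels = pd.unique(s)
            for lvl in levels[1:]:  # first level is reference
                d = (s == lvl).to_numpy(dtype=float)
                cols.append(d - d.mean())
                names.append(f"{name}[{lvl}]")
                tech.append(is_tech)

    for c in technical.columns:
        add(technical[c], f"tech:{c}", True)
    for c in ("age", "gender", "stage", "site", "msi"):
        if c in clinical.columns:
            add(clinical[c], c, False)

    if not cols:
        return np.empty((len(technical), 0)), np.empty(0, bool), []
    X = np.column_stack(cols)
    return X, np.asarray(tech, bool), names


def correct_technical(gm: GeneMatrix, technical: pd.DataFrame,
                      clinical: pd.DataFrame) -> GeneMatrix:
    """Remove technical-covariate contributions from each gene.

    A single linear model per gene includes both technical terms (quality
    metric, processing batch, center) and clinical terms (age, gender,
    stage, site, MSI); only the fitted technical contributions are
    subtracted, so clinical biology is retained.  Aliased (rank-deficient)
    technical columns are dropped with a warning.
    """
    samples = gm.values.columns
    technical = technical.loc[samples]
    clinical = clinical.loc[samples]
    X, tech_mask, names = _design_columns(technical, clinical)
    if X.shape[1] == 0 or not tech_mask.any():
        logger.info("correct_technical(%s): no usable technical terms; "
                    "matrix unchanged", gm.dataset_id)
        return gm.copy_with(gm.values.copy(), "correct_technical(noop)")

    # drop aliased columns via pivoted QR
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        logger.warning("correct_technical(%s): dropping aliased terms %s",
                       gm.dataset_id, dropped)
        X = X[:, keep]
        tech_mask = tech_mask[keep]

    Xd = np.column_stack([np.ones(len(samples)), X])
    Y = gm.values.to_numpy()  # genes x samples
    B, *_ = np.linalg.lstsq(Xd, Y.T, rcond=None)  # (1+p) x genes
    tech_cols = np.nonzero(np.concatenate([[False], tech_mask]))[0]
    correction = Xd[:, tech_cols] @ B[tech_cols]  # samples x genes
    corrected = pd.DataFrame(Y - correction.T, index=gm.values.index,
                             columns=samples)
    return gm.copy_with(corrected, "correct_technical(linear)")


def impute_msi(gm: GeneMatrix, msi_signature: GeneSignature,
               clinical: pd.DataFrame) -> pd.DataFrame:
    """Fill missing MSI labels from a transcriptomic MSI score.

    Samples are scored with the scaled-mean signature score; the score
    distribution is split at the minimum-density valley between its two
    largest modes (two-component Gaussian-mixture fallback when unimodal).
    The mode on the side named by the signature's ``direction`` (default
    ``high=MSI``) is labeled MSI.  Known labels are never touched.
    """
    clinical = clinical.copy()
    missing = clinical["msi"].isna()
    if not missing.any():
        logger.info("impute_msi: no missing MSI labels; clinical unchanged")
        return clinical
    present = [g for g in msi_signature.genes if g in gm.values.index]
    if not present:
        raise ValueError("MSI signature genes absent from the matrix")
    scores = score_signature(gm.values, msi_signature).scores
    thr, method = bimodal_threshold(scores.to_numpy())
    if method != "kde_valley":
        logger.warning("impute_msi: score density not bimodal; %s fallback "
                       "used (threshold=%.3f)", method, thr)
    direction = msi_signature.direction or "high=MSI"
    high_label = direction.split("=", 1)[1]
    low_label = "MSS" if high_label == "MSI" else "MSI"
    filled = np.where(scores.loc[clinical.index[missing]] > thr,
                      high_label, low_label)
    clinical.loc[missing, "msi"] = filled
    clinical.attrs["msi_imputation"] = {"threshold": float(thr),
                                        "method": method,
                                        "n_filled": int(missing.sum())}
    return clinical


def _stratum_keys(clinical: pd.DataFrame) -> pd.DataFrame:
    keys = pd.DataFrame(index=clinical.index)
    keys["gender"] = clinical["gender"].astype(str)
    keys["age_bin"] = (clinical["age"] // 10).astype(int).astype(str)
    keys["msi"] = clinical["msi"].astype("object").where(
        clinical["msi"].notna(), "missing").astype(str)
    keys["stage"] = clinical["stage"].astype(str)
    return keys


def standardize_to_reference(gm: GeneMatrix, ref: GeneMatrix,
                             clinical: pd.DataFrame,
                             ref_clinical: pd.DataFrame,
                             seed: int) -> GeneMatrix:
    """Genewise standardization of a dataset to the reference series.

    A reference subsample of the target's size, matched on the joint
    gender x age-decade x MSI x stage distribution, is drawn (without
    replacement within strata; with replacement only when a stratum is
    exhausted).  Each gene is mapped ``x' = (x - m_t)/s_t * s_ref + m_ref``
    using subsample statistics, then clamped to the per-gene [min, max] of
    the *full* reference.  Empty reference strata borrow the nearest
    stratum, dropping MSI first, then stage.
    """
    rng = np.random.default_rng(seed)
    tkeys = _stratum_keys(clinical.loc[gm.values.columns])
    rkeys = _stratum_keys(ref_clinical.loc[ref.values.columns])

    levels = [["gender", "age_bin", "msi", "stage"],
              ["gender", "age_bin", "stage"],
              ["gender", "age_bin"],
              []]
    ref_groups = {tuple(lv): rkeys.groupby(lv).groups if lv else
                  {(): rkeys.index} for lv in levels}

    chosen: List = []
    for stratum, members in tkeys.groupby(list(levels[0])).groups.items():
        need = len(members)
        candidates = None
        for lv in levels:
            key = tuple(stratum[levels[0].index(c)] for c in lv) if lv else ()
            groups = ref_groups[tuple(lv)]
            if key in groups or lv == []:
                candidates = pd.Index(groups[key]) if lv else pd.Index(rkeys.index)
                if lv != levels[0]:
                    logger.warning(
                        "standardize_to_reference(%s): stratum %s empty in "
                        "reference; borrowing %s", gm.dataset_id, stratum,
                        lv or "whole reference")
                break
        assert candidates is not None
        if len(candidates) >= need:
            pick = rng.choice(len(candidates), size=need, replace=False)
        else:
            logger.warning(
                "standardize_to_reference(%s): stratum %s larger than "
                "reference stratum; sampling with replacement",
                gm.dataset_id, stratum)
            pick = rng.choice(len(candidates), size=need, replace=True)
        chosen.extend(candidates[pick])

    shared = gm.values.index.intersection(ref.values.index)
    tgt = gm.values.loc[shared]
    refsub = ref.values.loc[shared, chosen]
    t_mean = tgt.mean(axis=1)
    t_sd = tgt.std(axis=1, ddof=1)
    r_mean = refsub.mean(axis=1)
    r_sd = refsub.std(axis=1, ddof=1)

    zero_var = t_sd == 0
    safe_sd = t_sd.where(~zero_var, 1.0)
    z = tgt.sub(t_mean, axis=0).div(safe_sd, axis=0)
    out = z.mul(r_sd, axis=0).add(r_mean, axis=0)
    if zero_var.any():
        logger.warning("standardize_to_reference(%s): %d zero-variance genes "
                       "mapped to the reference-subsample mean",
                       gm.dataset_id, int(zero_var.sum()))
        out.loc[zero_var] = np.broadcast_to(
            r_mean[zero_var].to_numpy()[:, None],
            (int(zero_var.sum()), out.shape[1]))

    full_min = ref.values.loc[shared].min(axis=1)
    full_max = ref.values.loc[shared].max(axis=1)
    out = out.clip(lower=full_min, upper=full_max, axis=0)
    return gm.copy_with(out, f"standardize_to_reference({ref.dataset_id},seed={seed})")


def merge_cohort(gene_matrices: Sequence[GeneMatrix],
                 clinical_tables: Sequence[pd.DataFrame],
                 reference_id: str) -> HarmonizedCohort:
    """Column-concatenate standardized datasets over their shared genes."""
    by_id = {gm.dataset_id: gm for gm in gene_matrices}
    if reference_id not in by_id:
        raise ValueError(f"reference dataset {reference_id!r} not among inputs")
    shared = gene_matrices[0].values.index
    for gm in gene_matrices[1:]:
        shared = shared.intersection(gm.values.index)
    all_samples = pd.Index(np.concatenate(
        [gm.values.columns for gm in gene_matrices]))
    if all_samples.duplicated().any():
        dups = all_samples[all_samples.duplicated()].unique()
        raise ValueError(f"duplicated sample ids across datasets: {list(dups)[:5]}")
    values = pd.concat([gm.values.loc[shared] for gm in gene_matrices], axis=1)
    clinical = pd.concat(list(clinical_tables), axis=0)
    clinical = clinical.loc[values.columns]
    ref = by_id[reference_id]
    bounds = pd.DataFrame({
        "min": ref.values.loc[shared].min(axis=1),
        "max": ref.values.loc[shared].max(axis=1),
    })
    return HarmonizedCohort(values=values, clinical=clinical,
                            reference_dataset_id=reference_id,
                            gene_bounds=bounds)
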