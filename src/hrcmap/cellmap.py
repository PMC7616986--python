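"""Mapping bulk-derived signatures onto single-cell data.

The chain is: QC filtering and median-library log normalization
(:func:`preprocess_cells`), graph-diffusion imputation with an adaptive
Gaussian kernel (:func:`diffusion_impute` — powers of a cell-cell Markov
operator), epithelial-cell calling from the connected components of the
kNN graph via imputed EPCAM (:func:`identify_epithelial`), per-cell
signature scores as the mean imputed expression of signature genes
(:func:`score_cells`), percentile-threshold classification into
HRC / LGR5+ / double-positive / other (:func:`classify_cells`),
per-patient composition, marker detection, and the correlation-ranked
core program (:func:`derive_core_signature`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

from ._utils import bimodal_threshold
from .scoring import GeneSignature

logger = logging.getLogger("hrcmap")

MITO_PATTERN = r"^MT-"
RIBO_PATTERN = r"^RP[SL]"


@dataclass
class QCThresholds:
    """Cell and sample QC cutoffs (10X preset).

    ``max_counts`` is unused by default; the deep-plate preset
    (:meth:`plate_preset`) instead requires >20,000 counts per cell.
    """

    max_mito: float = 0.20
    min_counts: float = 1000.0
    max_counts: float = float("inf")
    min_genes: int = 200
    max_genes: int = 6000
    min_cells_per_sample: int = 500
    drop_ribo: bool = True

    @classmethod
    def plate_preset(cls) -> "QCThresholds":
        return cls(min_counts=20000.0, max_genes=10 ** 9)

    @classmethod
    def permissive(cls) -> "QCThresholds":
        """Identity on cells (all thresholds disabled)."""
        return cls(max_mito=1.0, min_counts=0.0, min_genes=0,
                   max_genes=10 ** 9, min_cells_per_sample=0, drop_ribo=False)


def preprocess_cells(raw: ad.AnnData,
                     thresholds: Optional[QCThresholds] = None,
                     target_library: Optional[float] = None,
                     normalize: bool = True) -> ad.AnnData:
    """QC-filter and normalize a raw count matrix.

    Drops cells with mitochondrial fraction > 20%, library < 1000 counts,
    or genes detected outside [200, 6000]; removes ribosomal genes by name;
    drops samples retaining fewer than 500 cells.  Surviving counts are
    scaled per cell to the median library size (of this matrix, or
    ``target_library`` when samples are normalized jointly) and
    log(1+x)-transformed; raw counts stay in ``layers["counts"]``.  With
    ``normalize=False`` only QC is applied (two-pass workflows compute the
    pooled median first).
    """
    thr = thresholds or QCThresholds()
    X = raw.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    counts_per_cell = np.asarray(X.sum(axis=1)).ravel()
    genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_genes = raw.var_names.str.match(MITO_PATTERN)
    mito_counts = np.asarray(X[:, np.nonzero(mito_genes)[0]].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(counts_per_cell > 0,
                             mito_counts / counts_per_cell, 0.0)

    checks = [
        ("max_mito", mito_frac <= thr.max_mito),
        ("min_counts", counts_per_cell >= thr.min_counts),
        ("max_counts", counts_per_cell <= thr.max_counts),
        ("min_genes", genes_per_cell >= thr.min_genes),
        ("max_genes", genes_per_cell <= thr.max_genes),
    ]
    keep = np.ones(raw.n_obs, dtype=bool)
    for _, ok in checks:
        keep &= ok
    if not keep.any():
        worst = max(checks, key=lambda c: (~c[1]).sum())[0]
        raise ValueError(f"all cells removed by QC (dominant filter: {worst})")

    adata = raw[keep].copy()
    adata.obs["total_counts"] = counts_per_cell[keep]
    adata.obs["n_genes"] = genes_per_cell[keep]
    adata.obs["mito_frac"] = mito_frac[keep]

    if thr.drop_ribo:
        ribo = adata.var_names.str.match(RIBO_PATTERN)
        if ribo.any():
            adata = adata[:, ~ribo].copy()

    if thr.min_cells_per_sample > 0 and "sample" in adata.obs:
        sizes = adata.obs["sample"].value_counts()
        bad = sizes.index[sizes < thr.min_cells_per_sample]
        if len(bad):
            logger.warning("preprocess_cells: dropping samples with <%d "
                           "cells: %s", thr.min_cells_per_sample, list(bad))
            adata = adata[~adata.obs["sample"].isin(bad)].copy()
        if adata.n_obs == 0:
            raise ValueError("all cells removed by QC (dominant filter: "
                             "min_cells_per_sample)")

    C = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    adata.layers["counts"] = C.copy()
    if normalize:
        normalize_cells(adata, target_library)
    return adata


def normalize_cells(adata: ad.AnnData,
                    target_library: Optional[float] = None) -> ad.AnnData:
    """Scale each cell to the (given or median) library size, then log1p."""
    C = adata.layers.get("counts")
    if C is None:
        C = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
        adata.layers["counts"] = C.copy()
    lib = np.asarray(C.sum(axis=1)).ravel()
    med = target_library if target_library is not None else (
        float(np.median(lib[lib > 0])) if (lib > 0).any() else 1.0)
    scale = np.where(lib > 0, med / np.maximum(lib, 1e-12), 0.0)
    norm = sp.diags(scale) @ C
    norm.data = np.log1p(norm.data)
    adata.X = norm.tocsr()
    adata.uns["normalization"] = {"method": "median-library log1p",
                                  "median_counts": float(med)}
    return adata


@dataclass
class SmoothedCellMatrix:
    """Diffusion-imputed cell x gene expression and the graph behind it."""

    values: pd.DataFrame          # cells x genes, imputed
    params: Dict[str, float]
    kernel: sp.spmatrix           # symmetric affinity (incl. self-loops)
    markov: Optional[sp.spmatrix] = None


def diffusion_impute(data, k: int = 15, ka: int = 5, alpha: float = 2.0,
                     t: int = 3, n_pcs: int = 20,
                     random_state: int = 0) -> SmoothedCellMatrix:
    """Graph-diffusion imputation on normalized expression.

    A kNN graph is built on the top principal components; the adaptive
    kernel is ``A_ij = exp(-(d_ij / sigma_i)^alpha)`` with ``sigma_i`` the
    distance to the ka-th neighbor; the symmetrized kernel is row-normalized
    into a Markov operator M and the output is ``M^t X``.  ``t=0`` returns
    the input exactly; every imputed value stays inside the observed
    per-gene range (rows of M^t are convex weights).
    """
    if isinstance(data, ad.AnnData):
        X = data.X.toarray() if sp.issparse(data.X) else np.asarray(data.X)
        frame = pd.DataFrame(X, index=data.obs_names, columns=data.var_names)
    elif isinstance(data, pd.DataFrame):
        frame = data
    else:
        frame = pd.DataFrame(np.asarray(data, dtype=float))
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"diffusion_impute needs >= k+1 = {k + 1} cells, got {n}")
    if not 1 <= ka <= k:
        raise ValueError("ka must lie in [1, k]")

    params = {"k": k, "ka": ka, "alpha": alpha, "t": t, "n_pcs": n_pcs}

    n_comp = min(n_pcs, n - 1, X.shape[1])
    Xc = X - X.mean(axis=0)
    if 0 < n_comp < X.shape[1]:
        from sklearn.decomposition import PCA
        emb = PCA(n_components=n_comp, svd_solver="auto",
                  random_state=random_state).fit_transform(Xc)
    else:
        emb = Xc

    from sklearn.neighbors import NearestNeighbors
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(emb)
    dist, ind = nn.kneighbors(emb)  # column 0 is the cell itself
    sigma = dist[:, min(ka, dist.shape[1] - 1)].copy()
    floor = np.finfo(float).eps
    dup = sigma <= 0
    if dup.any():
        logger.warning("diffusion_impute: %d cells with zero kernel width "
                       "(duplicates); flooring sigma at machine epsilon",
                       int(dup.sum()))
        sigma[dup] = floor

    w = np.exp(-(dist / sigma[:, None]) ** alpha)
    rows = np.repeat(np.arange(n), ind.shape[1])
    A = sp.csr_matrix((w.ravel(), (rows, ind.ravel())), shape=(n, n))
    A = (A + A.T) * 0.5
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    M = sp.diags(1.0 / np.maximum(rowsum, floor)) @ A

    out = X
    for _ in range(int(t)):
        out = M @ out
    values = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return SmoothedCellMatrix(values=values, params=params, kernel=A.tocsr(),
                              markov=M.tocsr())


def identify_epithelial(smoothed: SmoothedCellMatrix,
                        epcam_gene: str = "EPCAM") -> pd.Series:
    """Flag epithelial cells via imputed EPCAM over graph components.

    Connected components of the kNN graph are computed; a component is
    epithelial iff its median imputed EPCAM exceeds the two-mode split of
    the per-component medians.  With a single component the split is
    applied per cell instead (diagnostic logged).
    """
    if epcam_gene not in smoothed.values.columns:
        raise ValueError(f"{epcam_gene!r} absent from the smoothed matrix")
    epcam = smoothed.values[epcam_gene]
    n_comp, labels = connected_components(smoothed.kernel, directed=False)
    if n_comp >= 2:
        medians = np.array([np.median(epcam[labels == c])
                            for c in range(n_comp)])
        thr, method = bimodal_threshold(medians)
        epi_comp = np.nonzero(medians > thr)[0]
        mask = np.isin(labels, epi_comp)
        logger.info("identify_epithelial: %d/%d components epithelial "
                    "(threshold %.3f via %s)", len(epi_comp), n_comp, thr,
                    method)
    else:
        thr, method = bimodal_threshold(epcam.to_numpy())
        logger.warning("identify_epithelial: single graph component; "
                       "applying the %s threshold %.3f per cell", method, thr)
        mask = epcam.to_numpy() > thr
    return pd.Series(mask, index=smoothed.values.index, name="epithelial")


def score_cells(smoothed: SmoothedCellMatrix, sig: GeneSignature) -> pd.Series:
    """Per-cell mean imputed expression over signature genes (no rescaling)."""
    present = [g for g in sig.genes if g in smoothed.values.columns]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} in the matrix")
    return smoothed.values[present].mean(axis=1).rename(sig.name)


@dataclass
class CellClassLabels:
    """HRC / LGR5+ / double-positive / other calls and thresholds used."""

    labels: pd.Series
    thresholds: Dict[str, float]
    percentile: float = 75.0


def classify_cells(epihr_scores: pd.Series, lgr5_scores: pd.Series,
                   percentile: float = 75.0) -> CellClassLabels:
    """Threshold two signature scores at the stated percentile.

    The threshold is the linear-interpolation percentile of each score over
    the analysis set; calls use strict inequality: HRC = EpiHR>q & Lgr5<=q,
    LGR5pos = Lgr5>q & EpiHR<=q, double_positive = both, other = neither.
    Constant scores flag nothing for that signature.
    """
    if not epihr_scores.index.equals(lgr5_scores.index):
        raise ValueError("score vectors must cover the same cells")
    qe = float(np.percentile(epihr_scores, percentile))
    ql = float(np.percentile(lgr5_scores, percentile))
    for name, s in (("EpiHR", epihr_scores), ("Lgr5", lgr5_scores)):
        if np.ptp(s.to_numpy()) == 0:
            logger.warning("classify_cells: %s scores constant; no cell "
                           "exceeds the threshold", name)
    e = epihr_scores.to_numpy() > qe
    l = lgr5_scores.to_numpy() > ql
    labels = np.where(e & l, "double_positive",
                      np.where(e, "HRC", np.where(l, "LGR5pos", "other")))
    return CellClassLabels(labels=pd.Series(labels, index=epihr_scores.index),
                           thresholds={"EpiHR": qe, "Lgr5": ql},
                           percentile=percentile)


def composition(labels: CellClassLabels, patients: pd.Series,
                stages: Optional[pd.Series] = None
                ) -> Tuple[pd.DataFrame, Optional[dict]]:
    """Per-patient class fractions and a Kruskal-Wallis stage test on HRC."""
    df = pd.DataFrame({"label": labels.labels, "patient": patients})
    frac = (df.groupby("patient")["label"].value_counts(normalize=True)
            .unstack(fill_value=0.0))
    for cls in ("HRC", "LGR5pos", "double_positive", "other"):
        if cls not in frac.columns:
            frac[cls] = 0.0
    frac = frac[["HRC", "LGR5pos", "double_positive", "other"]]
    kw = None
    if stages is not None:
        stage_of = stages.groupby(stages.index).first() if stages.index.has_duplicates \
            else stages
        merged = frac.join(stage_of.rename("stage"))
        groups = [g["HRC"].to_numpy() for _, g in merged.groupby("stage")]
        if len(groups) >= 2 and all(len(g) for g in groups):
            stat, p = stats.kruskal(*groups)
            kw = {"statistic": float(stat), "p": float(p),
                  "n_groups": len(groups)}
    return frac, kw


def find_markers(norm: pd.DataFrame, labels: Sequence, target: str,
                 min_detect_frac: float = 0.10, min_lfc: float = 0.25,
                 fdr: float = 0.05, log_base: str = "natural") -> pd.DataFrame:
    """Wilcoxon rank-sum markers of ``target`` cells vs the rest.

    ``norm`` is cells x genes normalized expression.  Candidates must be
    detected in >10% of target cells and show |log fold change| > 0.25 on
    (mean + 1); candidates are tested two-sided with BH adjustment and
    flagged at the requested FDR.
    """
    labels = np.asarray(labels)
    tmask = labels == target
    if tmask.sum() < 3:
        raise ValueError(f"target class {target!r} has <3 cells")
    X = norm.to_numpy(dtype=float)
    Xt, Xr = X[tmask], X[~tmask]
    detect = (Xt > 0).mean(axis=0)
    logf = np.log if log_base == "natural" else np.log2
    lfc = logf(Xt.mean(axis=0) + 1.0) - logf(Xr.mean(axis=0) + 1.0)
    cand = (detect > min_detect_frac) & (np.abs(lfc) > min_lfc)
    if not cand.any():
        logger.info("find_markers: no candidate genes pass the filters")
        return pd.DataFrame(columns=["lfc", "frac_target", "frac_rest", "p",
                                     "p_bh", "significant"])
    ci = np.nonzero(cand)[0]
    res = stats.mannwhitneyu(Xt[:, ci], Xr[:, ci], axis=0,
                             alternative="two-sided", method="asymptotic")
    from statsmodels.stats.multitest import multipletests
    p_bh = multipletests(res.pvalue, method="fdr_bh")[1]
    out = pd.DataFrame({
        "lfc": lfc[ci],
        "frac_target": detect[ci],
        "frac_rest": (Xr[:, ci] > 0).mean(axis=0),
        "p": res.pvalue,
        "p_bh": p_bh,
        "significant": p_bh < fdr,
    }, index=norm.columns[ci])
    return out.sort_values("p")


def signature_gene_correlations(smoothed_per_sample: Sequence[SmoothedCellMatrix],
                                scores_per_sample: Sequence[pd.Series]
                                ) -> pd.Series:
    """Average per-sample Pearson correlation of every gene with a score.

    Within each sample the correlation is computed across cells between
    each gene's imputed expression and the signature score; per-gene values
    are averaged over the samples where the gene varies.  Genes constant in
    every sample are excluded.
    """
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for sm, sc in zip(smoothed_per_sample, scores_per_sample):
        if sm.values.shape[0] < 10:
            logger.info("signature_gene_correlations: sample with <10 cells "
                        "skipped")
            continue
        X = sm.values.to_numpy(dtype=float)
        s = sc.reindex(sm.values.index).to_numpy(dtype=float)
        s_c = s - s.mean()
        s_norm = np.sqrt((s_c ** 2).sum())
        if s_norm == 0:
            continue
        Xc = X - X.mean(axis=0)
        gnorm = np.sqrt((Xc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ s_c) / (gnorm * s_norm)
        for g, ri, gn in zip(sm.values.columns, r, gnorm):
            if gn == 0:
                continue
            sums[g] = sums.get(g, 0.0) + float(ri)
            counts[g] = counts.get(g, 0) + 1
    if not sums:
        raise ValueError("no sample with >=10 cells and a varying score")
    avg = pd.Series({g: sums[g] / counts[g] for g in sums})
    return avg.sort_values(ascending=False)


def derive_core_signature(avg_correlations: pd.Series, k: int = 100,
                          name: str = "coreHRC") -> GeneSignature:
    """Top-k genes by average correlation with the signature score."""
    ranked = avg_correlations.sort_values(ascending=False)
    if len(ranked) < k:
        logger.warning("derive_core_signature: only %d ranked genes (<%d); "
                       "returning all", len(ranked), k)
        k = len(ranked)
    return GeneSignature(name=name, genes=list(ranked.index[:k]),
                         derivation=f"top {k} by average per-sample "
                                    "correlation with the signature score")


def dual_dataset_core(corr_a: pd.Series, corr_b: pd.Series,
                      threshold: float = 0.8) -> List[str]:
    """Genes exceeding the correlation threshold in both datasets."""
    shared = corr_a.index.intersection(corr_b.index)
    ok = (corr_a.loc[shared] > threshold) & (corr_b.loc[shared] > threshold)
    return list(shared[ok])
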