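"""Association and enrichment statistics around the HRC findings.

Covers: Spearman association between HRC abundance and microenvironment
populations (exact permutation p for small n), Wilcoxon comparisons of the
EpiHR score between mutant and wild-type samples, correlation-based
hierarchical clustering of signature genes, the maxmean competitive
gene-set statistic under restandardization with random-gene-set nulls, a
weighted Kolmogorov-Smirnov preranked enrichment score, and compositional
(CLR) trend models for multiplex-imaging cell counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger("hrcmap")


# ---------------------------------------------------------------------------
# Spearman association with exact small-sample permutation p
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (all n! relabelings)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    if denom == 0:
        return np.nan
    observed = abs((rx_c * ry_c).sum() / denom)
    count = 0
    total = 0
    chunk: List[Sequence[int]] = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 40320:
            count += _count_extreme(np.array(chunk), rx_c, ry_c, denom, observed)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _count_extreme(np.array(chunk), rx_c, ry_c, denom, observed)
        total += len(chunk)
    return count / total


def _count_extreme(perms: np.ndarray, rx_c: np.ndarray, ry_c: np.ndarray,
                   denom: float, observed: float) -> int:
    rhos = np.abs((ry_c[perms] * rx_c).sum(axis=1) / denom)
    return int((rhos >= observed - 1e-12).sum())


def spearman_association(x: Sequence[float], y: Sequence[float],
                         exact_max_n: int = 10) -> Dict[str, float]:
    """Spearman rho with exact permutation p for n <= exact_max_n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": np.nan, "p": np.nan, "n": n,
                "method": "undefined (constant vector)"}
    rho, p_asym = stats.spearmanr(x, y)
    if n <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
        method = "exact permutation"
    else:
        p, method = p_asym, "asymptotic"
    return {"rho": float(rho), "p": float(p), "n": n, "method": method}


def tme_association(hrc_fraction: pd.Series,
                    tme_fractions: pd.DataFrame) -> pd.DataFrame:
    """Spearman association of each TME population's abundance with HRCs.

    ``hrc_fraction`` and the columns of ``tme_fractions`` are per-sample
    percentages (or fractions).  Constant vectors yield NA with a reason.
    """
    shared = hrc_fraction.index.intersection(tme_fractions.index)
    if len(shared) < 5:
        raise ValueError("tme_association needs >=5 samples")
    rows = []
    for pop in tme_fractions.columns:
        res = spearman_association(tme_fractions.loc[shared, pop],
                                   hrc_fraction.loc[shared])
        rows.append({"population": pop, **res})
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# mutation association
# ---------------------------------------------------------------------------

def associate_mutations(scores: pd.Series, genotypes: pd.DataFrame,
                        min_group: int = 3) -> pd.DataFrame:
    """Wilcoxon rank-sum of a score between mutant and wild-type samples.

    One two-sided test per alteration; the effect is the difference of
    medians (mutant - wild-type).  Alterations with fewer than
    ``min_group`` samples in either group are skipped.
    """
    shared = scores.index.intersection(genotypes.index)
    rows = []
    for alt in genotypes.columns:
        g = genotypes.loc[shared, alt].astype(int)
        mut = scores.loc[shared[g == 1]]
        wt = scores.loc[shared[g == 0]]
        if len(mut) < min_group or len(wt) < min_group:
            logger.info("associate_mutations: %s skipped (group sizes %d/%d)",
                        alt, len(mut), len(wt))
            continue
        method = "exact" if min(len(mut), len(wt)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(mut, wt, alternative="two-sided",
                                 method=method)
        rows.append({"alteration": alt,
                     "median_difference": float(mut.median() - wt.median()),
                     "p": float(res.pvalue),
                     "n_mut": len(mut), "n_wt": len(wt)})
    return pd.DataFrame(rows).set_index("alteration") if rows else \
        pd.DataFrame(columns=["median_difference", "p", "n_mut", "n_wt"])


# ---------------------------------------------------------------------------
# correlation clustering of signature genes
# ---------------------------------------------------------------------------

@dataclass
class GeneClusterResult:
    assignments: pd.Series        # initial cluster id per gene (1..k)
    merged: pd.Series             # after merging the top clusters
    linkage_tree: np.ndarray
    merged_clusters: List[int]


def cluster_signature_genes(matrix: pd.DataFrame, sig, k: int = 6,
                            merge_top: int = 3,
                            criterion: str = "intra") -> GeneClusterResult:
    """Complete-linkage clustering of signature genes on 1 - Pearson r.

    The gene x gene correlation over samples defines distance ``1 - r``;
    the tree is cut into ``k`` clusters and the ``merge_top`` clusters with
    the highest mean intra-cluster pairwise correlation (singletons rank
    lowest) are merged into one cluster labeled 1.  ``criterion="inter"``
    instead picks the group of clusters with the highest mean pairwise
    correlation between their members.
    """
    genes = [g for g in sig.genes if g in matrix.index]
    if len(genes) < k:
        raise ValueError(f"k={k} exceeds the {len(genes)} available genes")
    sub = matrix.loc[genes]
    corr = np.corrcoef(sub.to_numpy())
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    assign = fcluster(Z, t=k, criterion="maxclust")
    assign = pd.Series(assign, index=genes)

    cluster_ids = sorted(assign.unique())

    def intra_mean(ids: Sequence[int]) -> float:
        members = np.nonzero(assign.isin(ids).to_numpy())[0]
        if len(members) < 2:
            return -np.inf
        block = corr[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        return float(block[iu].mean())

    if criterion == "intra":
        ranked = sorted(cluster_ids, key=lambda c: intra_mean([c]),
                        reverse=True)
        top = ranked[:merge_top]
    elif criterion == "inter":
        best, top = -np.inf, cluster_ids[:merge_top]
        for combo in itertools.combinations(cluster_ids, merge_top):
            m = intra_mean(list(combo))
            if m > best:
                best, top = m, list(combo)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    merged = assign.copy()
    merged[assign.isin(top)] = 1
    # relabel remaining clusters 2.. in order of appearance
    next_id = 2
    for c in cluster_ids:
        if c not in top:
            merged[assign == c] = next_id
            next_id += 1
    return GeneClusterResult(assignments=assign, merged=merged,
                             linkage_tree=Z, merged_clusters=list(top))


# ---------------------------------------------------------------------------
# maxmean competitive enrichment with restandardization
# ---------------------------------------------------------------------------

def maxmean_statistic(z: np.ndarray) -> float:
    """Maxmean: the larger (in magnitude) of the mean positive and mean
    negative parts of the member statistics, signed accordingly."""
    s_pos = np.maximum(z, 0.0).mean()
    s_neg = np.maximum(-z, 0.0).mean()
    return float(s_pos if s_pos >= s_neg else -s_neg)


def maxmean_enrichment(gene_stats: pd.Series, gene_sets: Dict[str, Sequence[str]],
                       n_perm: int = 1000, seed: int = 0,
                       min_size: int = 5) -> pd.DataFrame:
    """Competitive gene-set testing with the restandardized maxmean statistic.

    For each set the raw maxmean of its member statistics is compared
    against random gene sets of the same size drawn from the whole
    universe; the restandardized value is ``(raw - mean_null) / sd_null``.
    Following the two-column convention of competitive gene-set tests,
    ``p`` is the upper (positive-enrichment) tail ``P(null >= raw)`` and
    ``p_low`` the lower tail, each calibrated at its nominal level (ties
    counted; exhaustive over all subsets when that is cheaper than
    ``n_perm`` draws).  BH adjustment across sets applies to ``p``.
    """
    z = gene_stats.to_numpy(dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("gene statistics must be finite")
    universe = gene_stats.index
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        idx = universe.get_indexer([m for m in members if m in universe])
        idx = idx[idx >= 0]
        m = len(idx)
        if m < min_size:
            logger.info("maxmean_enrichment: set %s skipped (%d < %d genes)",
                        name, m, min_size)
            continue
        raw = maxmean_statistic(z[idx])
        from math import comb
        n_subsets = comb(len(universe), m) if m <= 20 else None
        if n_subsets is not None and n_subsets <= n_perm:
            null = np.array([maxmean_statistic(z[list(c)]) for c in
                             itertools.combinations(range(len(universe)), m)])
            p_hi = float((null >= raw - 1e-12).sum() / len(null))
            p_lo = float((null <= raw + 1e-12).sum() / len(null))
        else:
            draws = np.stack([rng.choice(len(universe), size=m, replace=False)
                              for _ in range(n_perm)])
            zn = z[draws]
            s_pos = np.maximum(zn, 0.0).mean(axis=1)
            s_neg = np.maximum(-zn, 0.0).mean(axis=1)
            null = np.where(s_pos >= s_neg, s_pos, -s_neg)
            p_hi = float((1 + (null >= raw - 1e-12).sum()) / (1 + n_perm))
            p_lo = float((1 + (null <= raw + 1e-12).sum()) / (1 + n_perm))
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        restd = (raw - mu) / sd if sd > 0 else 0.0
        rows.append({"set": name, "maxmean": raw, "restandardized": restd,
                     "p": min(max(p_hi, np.nextafter(0, 1)), 1.0),
                     "p_low": min(max(p_lo, np.nextafter(0, 1)), 1.0),
                     "size": m})
    res = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["maxmean", "restandardized", "p", "p_low", "size"])
    if len(res):
        from statsmodels.stats.multitest import multipletests
        res["p_bh"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


# ---------------------------------------------------------------------------
# preranked (weighted KS) enrichment
# ---------------------------------------------------------------------------

def _enrichment_score(order_stats: np.ndarray, hit: np.ndarray,
                      weight: float) -> float:
    """Signed max-deviation running sum over a ranked gene list."""
    n = len(order_stats)
    n_hit = int(hit.sum())
    n_miss = n - n_hit
    if n_miss == 0 or n_hit == 0:
        return 0.0
    w = np.abs(order_stats) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member statistics are zero with weight > 0
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit).astype(float) / n_miss
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def preranked_enrichment(gene_stats: pd.Series,
                         gene_sets: Dict[str, Sequence[str]],
                         weight: float = 1.0, n_perm: int = 1000,
                         seed: int = 0, min_size: int = 5) -> pd.DataFrame:
    """Preranked enrichment with the weighted Kolmogorov-Smirnov score.

    Genes are ranked by the statistic (descending; ties broken by gene id
    for a stable order).  NES normalizes the enrichment score by the mean
    |null ES| of the same sign under random membership; p is the same-sign
    permutation tail; BH across sets.
    """
    if not np.isfinite(gene_stats.to_numpy(dtype=float)).all():
        raise ValueError("gene statistics must be finite")
    df = pd.DataFrame({"stat": gene_stats.to_numpy(dtype=float),
                       "gene": gene_stats.index.to_numpy()})
    df = df.sort_values(["stat", "gene"], ascending=[False, True])
    order_stats = df["stat"].to_numpy(dtype=float)
    order_genes = df["gene"].to_numpy()
    n = len(order_genes)
    pos = {g: i for i, g in enumerate(order_genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        hit_idx = np.array(sorted(pos[m] for m in members if m in pos),
                           dtype=int)
        m = len(hit_idx)
        if m < min_size:
            logger.info("preranked_enrichment: set %s skipped (%d < %d)",
                        name, m, min_size)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[hit_idx] = True
        es = _enrichment_score(order_stats, hit, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            h = np.zeros(n, dtype=bool)
            h[rng.choice(n, size=m, replace=False)] = True
            null[b] = _enrichment_score(order_stats, h, weight)
        same = null[null >= 0] if es >= 0 else -null[null < 0]
        if same.size == 0 or same.mean() == 0:
            nes, p = 0.0, 1.0
        else:
            nes = abs(es) / same.mean() * (1 if es >= 0 else -1)
            p = float((1 + (same >= abs(es) - 1e-12).sum()) / (1 + same.size))
        rows.append({"set": name, "es": es, "nes": nes, "p": p, "size": m})
    res = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["es", "nes", "p", "size"])
    if len(res):
        from statsmodels.stats.multitest import multipletests
        res["p_bh"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


# ---------------------------------------------------------------------------
# compositional (CLR) trend analysis
# ---------------------------------------------------------------------------

def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio of per-observation composition (rows sum to 0)."""
    x = counts.to_numpy(dtype=float) + pseudocount
    props = x / x.sum(axis=1, keepdims=True)
    logp = np.log(props)
    clr = logp - logp.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def clr_composition_trend(counts: pd.DataFrame, size: pd.Series,
                          burden: pd.Series, tumor_id: pd.Series,
                          pseudocount: float = 0.5) -> Dict[str, object]:
    """Per-population linear trend of CLR abundance with metastasis size.

    For each population the model is ``CLR ~ log2(size) + burden`` with a
    tumor-level random intercept (plain OLS fallback when every tumor
    contributes a single metastasis).  Also returns the burden-averaged
    composition table used for stacked-area summaries.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >=2 populations")
    if counts.shape[0] < 3:
        raise ValueError("need >=3 metastases")
    present = counts.columns[(counts.sum(axis=0) > 0)]
    dropped = [c for c in counts.columns if c not in set(present)]
    if dropped:
        logger.warning("clr_composition_trend: populations absent everywhere "
                       "dropped: %s", dropped)
    counts = counts[present]
    clr = clr_transform(counts, pseudocount)

    data = pd.DataFrame({
        "log2size": np.log2(size.loc[counts.index].to_numpy(dtype=float)),
        "burden": burden.loc[counts.index].astype(str),
        "tumor": tumor_id.loc[counts.index].astype(str),
    }, index=counts.index)
    singleton_groups = data["tumor"].value_counts().max() == 1

    import statsmodels.formula.api as smf
    rows = []
    for pop in counts.columns:
        d = data.copy()
        d["y"] = clr[pop]
        formula = "y ~ log2size + C(burden)"
        if singleton_groups:
            fit = smf.ols(formula, data=d).fit()
        else:
            try:
                fit = smf.mixedlm(formula, data=d, groups=d["tumor"]).fit(
                    reml=True, method="lbfgs")
            except Exception:  # singular random-effect fit
                logger.warning("clr_composition_trend: mixed model failed for "
                               "%s; OLS fallback", pop)
                fit = smf.ols(formula, data=d).fit()
        rows.append({"population": pop,
                     "size_coef": float(fit.params["log2size"]),
                     "size_p": float(fit.pvalues["log2size"]),
                     **{f"burden_{t.split('T.')[-1].rstrip(']')}":
                        float(fit.params[t]) for t in fit.params.index
                        if t.startswith("C(burden)")}})
    trend = pd.DataFrame(rows).set_index("population")

    props = counts.to_numpy(dtype=float)
    props = props / props.sum(axis=1, keepdims=True)
    props = pd.DataFrame(props, index=counts.index, columns=counts.columns)
    avg = props.groupby(burden.loc[counts.index].astype(str)).mean()
    return {"trend": trend, "clr": clr, "average_composition": avg}
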