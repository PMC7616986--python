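"""Gene signatures and sample-level signature scores.

The score used throughout the bulk analyses is the *scaled mean*: each gene
is z-scored across samples (sample SD, ddof=1), the per-sample score is the
mean of those z-values over the signature genes, and the resulting score
vector is re-standardized to mean 0 / SD 1 so that effect sizes read as
"per +1 SD of the signature".

A second convention (:func:`zscore_signature_replicates`) serves designed
experiments with biological replicates: expression is residualized on the
replicate factor, z-scored genewise, summarized per signature, and centered
a priori by subtracting the global all-gene score — this removes systematic
sample-level shifts that would otherwise bias every signature the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hrcmap")


@dataclass
class GeneSignature:
    """A named, ordered gene list with derivation provenance."""

    name: str
    genes: List[str]
    derivation: str = ""
    direction: Optional[str] = None  # e.g. "high=MSI"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureScores:
    """Per-sample signature scores in SD units."""

    scores: pd.Series
    signature: str
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)


def score_signature(matrix: pd.DataFrame, sig: GeneSignature) -> SignatureScores:
    """Scaled-mean signature score over a gene x sample matrix.

    Genes are z-scored across samples; the per-sample score is the mean of
    the z-values over the signature genes present in the matrix; scores are
    re-standardized to mean 0, SD 1.  Zero-variance genes are dropped with
    a warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError("score_signature needs >=3 samples")
    present = [g for g in sig.genes if g in matrix.index]
    if not present:
        raise ValueError(
            f"no gene of signature {sig.name!r} present in the matrix")
    sub = matrix.loc[present]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(sub.index[~keep])
        logger.warning("score_signature(%s): dropping %d zero-variance genes: %s",
                       sig.name, len(dropped), dropped[:5])
        sub = sub.loc[keep]
        sd = sd.loc[keep]
        if sub.empty:
            raise ValueError(
                f"all genes of signature {sig.name!r} are constant")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    raw = z.mean(axis=0)
    s = raw.std(ddof=1)
    if s == 0:
        raise ValueError("signature score is constant across samples")
    scores = (raw - raw.mean()) / s
    return SignatureScores(
        scores=scores,
        signature=sig.name,
        provenance=[f"genes_used={sub.shape[0]}/{len(sig.genes)}",
                    "genewise_zscore(ddof=1)", "mean", "restandardized"],
    )


def zscore_signature_replicates(matrix: pd.DataFrame, sig: GeneSignature,
                                replicates: Sequence) -> SignatureScores:
    """Replicate-adjusted, globally centered signature z-score.

    Each gene is residualized on the biological-replicate factor (per-level
    means removed, grand mean restored), z-scored genewise, and the
    signature score is the mean over constituent genes minus the global
    score computed from *all* genes (a priori centering).
    """
    replicates = pd.Series(list(replicates), index=matrix.columns)
    if replicates.nunique() < 2:
        logger.info("zscore_signature_replicates: single replicate level; "
                    "residualization is a no-op")
        adj = matrix
    else:
        adj = matrix.copy()
        grand = adj.mean(axis=1)
        for level, cols in replicates.groupby(replicates).groups.items():
            block = adj.loc[:, cols]
            adj.loc[:, cols] = block.sub(block.mean(axis=1), axis=0)
        adj = adj.add(grand, axis=0)
    sd = adj.std(axis=1, ddof=1)
    keep = sd > 0
    z = adj.loc[keep].sub(adj.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    present = [g for g in sig.genes if g in z.index]
    if not present:
        raise ValueError(f"no usable gene of signature {sig.name!r}")
    global_score = z.mean(axis=0)
    sig_score = z.loc[present].mean(axis=0) - global_score
    return SignatureScores(
        scores=sig_score,
        signature=sig.name,
        provenance=["replicate_residualized", "genewise_zscore(ddof=1)",
                    "mean", "global_centered"],
    )
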