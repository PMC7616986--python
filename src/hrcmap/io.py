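"""Readers/writers for the plain-text interchange formats of the pipeline.

Expression matrices and clinical/survival tables travel as TSV, gene
signatures as GMT, single-cell counts as MatrixMarket MTX with genes/
barcodes sidecars, and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .scoring import GeneSignature


def write_gmt(signatures: Sequence[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            desc = sig.derivation or "na"
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


def read_gmt(path) -> List[GeneSignature]:
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sigs.append(GeneSignature(name=parts[0], genes=parts[2:],
                                      derivation=parts[1]))
    return sigs


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sc_sample(adata: ad.AnnData, outdir) -> None:
    """MTX (genes x cells) + genes.tsv + barcodes.tsv + cell metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t",
                     index_label="barcode")


def read_sc_sample(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(indir / "cell_metadata.tsv", sep="\t", index_col=0)
    obs = obs.loc[barcodes]
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=list(genes)))


def write_ground_truth(truth, path) -> None:
    """JSON dump of a GroundTruth object (Series become dicts)."""
    payload: Dict[str, object] = {}
    for name, value in vars(truth).items():
        if value is None:
            continue
        if isinstance(value, pd.Series):
            payload[name] = {str(k): _jsonify(v) for k, v in value.items()}
        elif isinstance(value, pd.DataFrame):
            payload[name] = {c: {str(k): _jsonify(v) for k, v in
                                 value[c].items()} for c in value.columns}
        else:
            payload[name] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
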