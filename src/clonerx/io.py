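"""Reading and writing the standard on-disk formats.

Counts travel as a 10x-style MTX triplet (``matrix.mtx`` genes x cells,
``features.tsv``, ``barcodes.tsv``) plus a BED-like ``gene_map.tsv`` carrying
genomic coordinates, or as a dense genes x cells CSV.  Reference tables are
plain CSV with the schemas produced by :mod:`clonerx.sim`.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_counts_mtx",
    "read_counts",
    "write_reference_tables",
    "read_reference_tables",
]


def write_counts_mtx(adata: ad.AnnData, out_dir: str) -> None:
    """Write a cells x genes AnnData as a 10x-style MTX triplet."""
    os.makedirs(out_dir, exist_ok=True)
    mat = adata.X
    if not sparse.issparse(mat):
        mat = sparse.csr_matrix(mat)
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat.T.tocoo(), field="integer")
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(os.path.join(out_dir, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    cols = [c for c in ("chromosome", "arm", "start") if c in adata.var.columns]
    if cols:
        adata.var[cols].to_csv(os.path.join(out_dir, "gene_map.tsv"), sep="\t")


def read_counts(path: str) -> ad.AnnData:
    """Read counts from an MTX triplet directory or a dense genes x cells CSV."""
    if os.path.isdir(path):
        mat = spio.mmread(os.path.join(path, "matrix.mtx")).tocsr().T.tocsr()
        feats = pd.read_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=None
        )
        barcodes = pd.read_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=None
        )[0].astype(str)
        var = pd.DataFrame(index=pd.Index(feats[0].astype(str), name="symbol"))
        gene_map = os.path.join(path, "gene_map.tsv")
        if os.path.exists(gene_map):
            gm = pd.read_csv(gene_map, sep="\t", index_col=0)
            var = var.join(gm)
        adata = ad.AnnData(
            X=mat.astype(np.int64),
            obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
            var=var,
        )
        return adata
    dense = pd.read_csv(path, index_col=0)
    return ad.AnnData(
        X=sparse.csr_matrix(dense.to_numpy().T.astype(np.int64)),
        obs=pd.DataFrame(index=pd.Index(dense.columns.astype(str), name="barcode")),
        var=pd.DataFrame(index=pd.Index(dense.index.astype(str), name="symbol")),
    )


def write_reference_tables(out_dir, perturbations, curves, fingerprints, truth=None):
    os.makedirs(out_dir, exist_ok=True)
    perturbations.to_csv(os.path.join(out_dir, "perturbations.csv"), index=False)
    curves.to_csv(os.path.join(out_dir, "curves.csv"), index=False)
    fingerprints.to_csv(os.path.join(out_dir, "fingerprints.csv"), index=False)
    if truth is not None:
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            fh.write(truth.to_json())


def read_reference_tables(in_dir):
    perturbations = pd.read_csv(os.path.join(in_dir, "perturbations.csv"))
    curves = pd.read_csv(os.path.join(in_dir, "curves.csv"))
    fingerprints = pd.read_csv(os.path.join(in_dir, "fingerprints.csv"))
    return perturbations, curves, fingerprints
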