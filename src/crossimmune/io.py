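"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as MatrixMarket coordinate triplets with barcodes.tsv
and features.tsv siblings (the 10x convention); tables as CSV; hit tables
as 12-column BLAST tabular TSV; trees as Newick.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .droplet_qc import CountMatrix

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_mtx_dir(m: CountMatrix, path: str | Path) -> Path:
    """Write matrix.mtx (genes x barcodes, integer), features.tsv, barcodes.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
    pd.Series(m.genes).to_csv(path / "features.tsv", sep="\t",
                              header=False, index=False)
    pd.Series(m.barcodes).to_csv(path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)
    return path


def read_mtx_dir(path: str | Path) -> CountMatrix:
    path = Path(path)
    counts = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].to_numpy(
        dtype=object
    )
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(
        dtype=object
    )
    return CountMatrix(genes, barcodes, counts)


def read_dense_csv(path: str | Path) -> CountMatrix:
    """Dense fallback: genes in rows (index), barcodes in columns."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        sp.csr_matrix(df.to_numpy()),
    )


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BLAST_COLUMNS, comment="#")


def write_blast_tab(hits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    return path


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")
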