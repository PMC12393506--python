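"""Readers/writers for the standard on-disk formats.

Single-cell counts travel as MatrixMarket (cells in rows) with two
delimited sidecar tables (genes.tsv; cells.tsv with columns cell_id,
cell_type, modality, donor), or as a dense delimited table with the same
cell annotation sidecar. Bulk matrices are plain TSV/CSV with samples in
rows. Source modality vocabularies (e.g. "sc"/"sn") can be mapped to the
canonical {cell, nucleus} tokens at read time.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import BulkMatrix, LabeledCounts, MODALITIES

_GENES = "genes.tsv"
_CELLS = "cells.tsv"
_MATRIX = "matrix.mtx"
_DENSE = "matrix.tsv"


def _map_modality(raw, modality_map):
    mapped = [modality_map.get(m, m) if modality_map else m for m in raw]
    bad = sorted(set(mapped) - set(MODALITIES))
    if bad:
        raise ValueError(f"unknown modality label(s) {bad}; provide a "
                         f"modality_map to {MODALITIES}")
    return np.array(mapped, dtype=object)


def write_counts(lc: LabeledCounts, path: str, format: str = "mtx") -> None:
    """Write a LabeledCounts to ``path`` (a directory) in mtx or dense form."""
    os.makedirs(path, exist_ok=True)
    pd.DataFrame({"gene_id": lc.gene_ids}).to_csv(
        os.path.join(path, _GENES), sep="\t", index=False)
    pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(lc.n_cells)],
        "cell_type": lc.cell_type,
        "modality": lc.modality,
        "donor": lc.donor,
    }).to_csv(os.path.join(path, _CELLS), sep="\t", index=False)
    if format == "mtx":
        mat = lc.values if sp.issparse(lc.values) else sp.csr_matrix(lc.values)
        scipy.io.mmwrite(os.path.join(path, _MATRIX), mat)
    elif format == "dense":
        pd.DataFrame(lc.dense(), columns=lc.gene_ids).to_csv(
            os.path.join(path, _DENSE), sep="\t", index=False,
            float_format="%.12g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_counts(path: str, format: str = "mtx", modality_map=None,
                dataset_tag: str = "") -> LabeledCounts:
    """Read a LabeledCounts written by :func:`write_counts`."""
    genes = pd.read_csv(os.path.join(path, _GENES), sep="\t")["gene_id"].values
    cells = pd.read_csv(os.path.join(path, _CELLS), sep="\t")
    if format == "mtx":
        values = scipy.io.mmread(os.path.join(path, _MATRIX)).tocsr()
    elif format == "dense":
        values = pd.read_csv(os.path.join(path, _DENSE), sep="\t").values
    else:
        raise ValueError(f"unknown format {format!r}")
    if values.shape[0] != len(cells):
        raise ValueError(
            f"matrix has {values.shape[0]} rows but cell sidecar has "
            f"{len(cells)} entries")
    if values.shape[1] != len(genes):
        raise ValueError(
            f"matrix has {values.shape[1]} columns but gene sidecar has "
            f"{len(genes)} entries")
    return LabeledCounts(
        values=values,
        gene_ids=genes,
        cell_type=cells["cell_type"].values,
        modality=_map_modality(cells["modality"].values, modality_map),
        donor=cells["donor"].values,
        dataset_tag=dataset_tag,
    )


def write_bulk(bulk: BulkMatrix, path: str, sep: str = "\t") -> None:
    """Write a bulk matrix as a delimited table, samples in rows."""
    df = pd.DataFrame(bulk.dense(), index=bulk.sample_ids,
                      columns=bulk.gene_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.12g")


def read_bulk(path: str, sep: str = "\t") -> BulkMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return BulkMatrix(values=df.values, gene_ids=df.columns.values,
                      sample_ids=df.index.values)
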