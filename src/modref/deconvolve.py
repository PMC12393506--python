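"""Bulk deconvolution against a reference panel.

The built-in solver is non-negative least squares on CPM-normalized
data: each reference cell is scaled to counts per million, the per-type
arithmetic mean forms the signature matrix, each bulk sample is CPM
scaled and solved with scipy's NNLS, and the weights are renormalized to
proportions. NNLS is deterministic and adequate for ranking reference
variants; a Bayesian tool can be substituted through the external
adapter, which exchanges plain CSV files (reference as genes × cells
with a type map, bulks as genes × samples, proportions back as
samples × types) and records the iteration count in its config.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import BulkMatrix
from .reference import ReferencePanel

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionResult:
    proportions: np.ndarray       # (n_samples, n_types), rows sum to 1
    cell_types: list
    sample_ids: np.ndarray
    solver: str
    residual_norms: np.ndarray

    def __post_init__(self):
        if np.any(self.proportions < 0):
            raise ValueError("proportions must be non-negative")
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, index=self.sample_ids,
                          columns=self.cell_types)
        df.index.name = "sample_id"
        return df

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, float_format="%.6f")


def cpm(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cannot CPM-normalize an all-zero row")
    return values * (1e6 / totals)


def build_signature(panel: ReferencePanel) -> np.ndarray:
    """Per-type mean of CPM-normalized reference cells, (n_types, n_genes)."""
    if panel.signature is not None:
        return panel.signature
    dense = panel.cells.dense().astype(float)
    norm = cpm(dense)
    types = panel.cell_types
    sig = np.vstack([norm[panel.cells.cell_type == t].mean(axis=0)
                     for t in types])
    return sig


def deconvolve(bulk: BulkMatrix, panel: ReferencePanel,
               backend: str = "nnls", backend_config: dict = None
               ) -> DeconvolutionResult:
    """Estimate cell-type proportions for every bulk sample."""
    if not np.array_equal(bulk.gene_ids, panel.gene_ids):
        raise ValueError("bulk and panel must be gene-aligned")
    if backend == "nnls":
        return _nnls_backend(bulk, panel)
    if backend == "external_adapter":
        cfg = backend_config or {}
        return run_external_adapter(bulk, panel, **cfg)
    raise ValueError(f"unknown backend {backend!r}")


def _nnls_backend(bulk: BulkMatrix, panel: ReferencePanel
                  ) -> DeconvolutionResult:
    sig = build_signature(panel)          # (n_types, n_genes)
    b = cpm(bulk.dense().astype(float))   # (n_samples, n_genes)
    A = sig.T                             # (n_genes, n_types)
    n_samples, n_types = b.shape[0], sig.shape[0]
    props = np.empty((n_samples, n_types))
    resid = np.empty(n_samples)
    for i in range(n_samples):
        w, r = nnls(A, b[i])
        total = w.sum()
        if total <= 0:
            logger.warning("degenerate NNLS solution for sample %s; "
                           "falling back to uniform proportions",
                           bulk.sample_ids[i])
            props[i] = 1.0 / n_types
        else:
            props[i] = w / total
        resid[i] = r
    return DeconvolutionResult(
        proportions=props, cell_types=panel.cell_types,
        sample_ids=bulk.sample_ids.copy(), solver="nnls",
        residual_norms=resid)


# ----------------------------------------------------------------------
# external adapter contract (e.g. an InstaPrism/BayesPrism wrapper)

def write_adapter_inputs(bulk: BulkMatrix, panel: ReferencePanel,
                         workdir: str, n_iterations: int = 5000) -> None:
    """Write the file-exchange inputs for an external deconvolution tool.

    Layout: reference.csv (genes × cells, raw counts), cell_types.csv
    (cell_id, cell_type), bulks.csv (genes × samples), config.json.
    """
    os.makedirs(workdir, exist_ok=True)
    cells = panel.cells
    ref = pd.DataFrame(cells.dense().T, index=cells.gene_ids,
                       columns=[f"cell{i}" for i in range(cells.n_cells)])
    ref.index.name = "gene_id"
    ref.to_csv(os.path.join(workdir, "reference.csv"))
    pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(cells.n_cells)],
        "cell_type": cells.cell_type,
    }).to_csv(os.path.join(workdir, "cell_types.csv"), index=False)
    bk = pd.DataFrame(bulk.dense().T, index=bulk.gene_ids,
                      columns=bulk.sample_ids)
    bk.index.name = "gene_id"
    bk.to_csv(os.path.join(workdir, "bulks.csv"))
    with open(os.path.join(workdir, "config.json"), "w") as fh:
        json.dump({"n_iterations": n_iterations,
                   "variant": panel.variant}, fh)


def read_adapter_output(workdir: str, bulk: BulkMatrix,
                        panel: ReferencePanel) -> DeconvolutionResult:
    """Read proportions.csv (samples × types) produced by the tool."""
    path = os.path.join(workdir, "proportions.csv")
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(bulk.sample_ids):
        raise ValueError("adapter output sample ids do not match the bulks")
    missing = set(panel.cell_types) - set(df.columns)
    if missing:
        raise ValueError(f"adapter output missing cell types {sorted(missing)}")
    props = df[panel.cell_types].values.astype(float)
    rowsum = props.sum(axis=1, keepdims=True)
    if np.any(rowsum <= 0) or np.any(props < 0):
        raise ValueError("adapter output proportions malformed")
    return DeconvolutionResult(
        proportions=props / rowsum, cell_types=panel.cell_types,
        sample_ids=bulk.sample_ids.copy(), solver="external_adapter",
        residual_norms=np.full(len(df), np.nan))


def run_external_adapter(bulk, panel, workdir=None, n_iterations: int = 5000):
    """File-exchange adapter: writes inputs, expects proportions.csv.

    Execution of the external tool itself is outside this package; this
    call succeeds only if the tool has already deposited its output.
    """
    if workdir is None:
        raise ValueError("external adapter requires a workdir")
    write_adapter_inputs(bulk, panel, workdir, n_iterations=n_iterations)
    return read_adapter_output(workdir, bulk, panel)
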