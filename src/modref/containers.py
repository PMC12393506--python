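"""Core data containers for labeled single-cell counts and bulk expression.

The two containers are deliberately thin: a values matrix plus aligned
metadata vectors, with value-level invariants checked at construction.
Matrices may be dense ndarrays or scipy sparse; all operations are
defined on values, not storage layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MODALITIES = ("cell", "nucleus")


def _as_2d(values):
    if sp.issparse(values):
        return values.tocsr()
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


def _min_value(values) -> float:
    if sp.issparse(values):
        return float(values.data.min()) if values.nnz else 0.0
    return float(values.min()) if values.size else 0.0


@dataclass
class LabeledCounts:
    """Cells × genes expression with per-cell type/modality/donor labels.

    Values are non-negative; raw counts are integers, transformed
    expression may be real.
    """

    values: object  # (n_cells, n_genes) ndarray or sparse
    gene_ids: np.ndarray
    cell_type: np.ndarray
    modality: np.ndarray
    donor: np.ndarray
    dataset_tag: str = ""

    def __post_init__(self):
        self.values = _as_2d(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.modality = np.asarray(self.modality, dtype=object)
        self.donor = np.asarray(self.donor, dtype=object)
        n_cells, n_genes = self.values.shape
        if n_cells < 1 or n_genes < 1:
            raise ValueError("LabeledCounts needs at least 1 cell and 1 gene")
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != n_genes {n_genes}"
            )
        if len(np.unique(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        for name, arr in (
            ("cell_type", self.cell_type),
            ("modality", self.modality),
            ("donor", self.donor),
        ):
            if len(arr) != n_cells:
                raise ValueError(f"{name} length {len(arr)} != n_cells {n_cells}")
        bad = set(np.unique(self.modality)) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modality labels {sorted(bad)}; "
                             f"expected subset of {MODALITIES}")
        if _min_value(self.values) < 0:
            raise ValueError("expression values must be non-negative")

    # -- basic views -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_cells(self, mask_or_idx) -> "LabeledCounts":
        idx = np.asarray(mask_or_idx)
        return LabeledCounts(
            values=self.values[idx],
            gene_ids=self.gene_ids.copy(),
            cell_type=self.cell_type[idx],
            modality=self.modality[idx],
            donor=self.donor[idx],
            dataset_tag=self.dataset_tag,
        )

    def subset_genes(self, idx) -> "LabeledCounts":
        idx = np.asarray(idx)
        return LabeledCounts(
            values=self.values[:, idx],
            gene_ids=self.gene_ids[idx],
            cell_type=self.cell_type.copy(),
            modality=self.modality.copy(),
            donor=self.donor.copy(),
            dataset_tag=self.dataset_tag,
        )

    def type_counts(self) -> dict:
        types, counts = np.unique(self.cell_type, return_counts=True)
        return dict(zip(types.tolist(), counts.tolist()))

    def library_sizes(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=1)).ravel()
        return self.values.sum(axis=1)


@dataclass
class BulkMatrix:
    """Samples × genes non-negative bulk expression (counts or TPM/CPM)."""

    values: object
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = _as_2d(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n_samples, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length mismatch")
        if len(np.unique(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length mismatch")
        if len(np.unique(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        if _min_value(self.values) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_genes(self, idx) -> "BulkMatrix":
        idx = np.asarray(idx)
        return BulkMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids[idx],
            sample_ids=self.sample_ids.copy(),
        )


def _gene_index(obj, shared: np.ndarray) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(obj.gene_ids)}
    return np.array([lookup[g] for g in shared], dtype=int)


def align_genes(*objs):
    """Restrict any number of count/bulk objects to their shared genes.

    Output gene order is lexicographic by gene id, identical across all
    outputs; inputs are left unmodified.
    """
    if len(objs) < 2:
        raise ValueError("align_genes needs at least two inputs")
    shared = set(objs[0].gene_ids.tolist())
    for o in objs[1:]:
        shared &= set(o.gene_ids.tolist())
    if not shared:
        names = [getattr(o, "dataset_tag", type(o).__name__) or type(o).__name__
                 for o in objs]
        raise ValueError(f"no shared genes between inputs {names}")
    order = np.array(sorted(shared), dtype=object)
    return tuple(o.subset_genes(_gene_index(o, order)) for o in objs)


def filter_min_cells(lc: LabeledCounts, partner: LabeledCounts,
                     min_cells: int = 50):
    """Drop cell types with fewer than ``min_cells`` cells in either input.

    Mirrors the standard pre-filter applied before reference/pseudobulk
    construction so that each retained type is sampled from a reasonably
    sized pool in both modalities.
    """
    counts_a = lc.type_counts()
    counts_b = partner.type_counts()
    all_types = sorted(set(counts_a) | set(counts_b))
    keep = [t for t in all_types
            if counts_a.get(t, 0) >= min_cells and counts_b.get(t, 0) >= min_cells]
    dropped = [t for t in all_types if t not in keep]
    if dropped:
        logger.info("filter_min_cells dropped types: %s", dropped)
    if not keep:
        raise ValueError(
            f"all cell types dropped at min_cells={min_cells}: {dropped}")
    keep_set = set(keep)
    mask_a = np.array([t in keep_set for t in lc.cell_type])
    mask_b = np.array([t in keep_set for t in partner.cell_type])
    return lc.subset_cells(mask_a), partner.subset_cells(mask_b)
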