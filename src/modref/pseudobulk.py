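"""Pseudobulk simulation with known cell-type proportions.

Two proportion schemes are supported:

* ``random`` — a flat Dirichlet (alpha = 1 for every type) draw over the
  simplex;
* ``realistic`` — empirical base proportions perturbed with Gaussian
  noise (sd 0.01) and renormalized.

Proportions are converted to integer cell counts over a fixed total
(default 1000 cells) by floor-then-largest-remainder allocation; any draw
that would assign a type zero cells is repeated. Cells are sampled
without replacement when the type has enough cells, profiles are summed,
entrywise Gaussian noise is added and negatives are clipped to zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .containers import BulkMatrix, LabeledCounts

logger = logging.getLogger(__name__)

_MAX_RESAMPLE = 1000


@dataclass
class PseudobulkSet:
    """Simulated mixtures with their ground-truth composition.

    ``manifest`` records, per pseudobulk, the exact cell row indices
    sampled from the source, so a zero-noise build can be reproduced
    bit-exactly by re-summing.
    """

    bulk: BulkMatrix
    proportions: np.ndarray       # (n_pb, n_types), rows sum to 1
    cell_counts: np.ndarray       # (n_pb, n_types) ints, rows sum to total
    cell_types: list
    scheme: np.ndarray            # per-sample {"random", "realistic"}
    manifest: list                # per-sample dict type -> [cell indices]
    seed: int
    total_cells: int

    def __post_init__(self):
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")
        if np.any(self.cell_counts.sum(axis=1) != self.total_cells):
            raise ValueError("cell count rows must sum to total_cells")
        if np.any(self.cell_counts <= 0):
            raise ValueError("cell_counts must have no zero entries")

    def save(self, bulk_path: str, proportions_path: str,
             manifest_path: str) -> None:
        from .io import write_bulk
        import pandas as pd
        write_bulk(self.bulk, bulk_path)
        df = pd.DataFrame(self.proportions, columns=self.cell_types,
                          index=self.bulk.sample_ids)
        df.index.name = "sample_id"
        df.to_csv(proportions_path)
        with open(manifest_path, "w") as fh:
            json.dump({
                "seed": self.seed,
                "total_cells": self.total_cells,
                "scheme": self.scheme.tolist(),
                "cells": [{k: list(map(int, v)) for k, v in m.items()}
                          for m in self.manifest],
            }, fh)


def _allocate_counts(props: np.ndarray, total: int) -> np.ndarray:
    """Floor allocation with largest-remainder top-up; sums exactly to total."""
    raw = props * total
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        counts[order[:short]] += 1
    return counts


def sample_proportions(scheme: str, cell_types, total_cells: int = 1000,
                       base=None, rng: np.random.Generator | None = None,
                       noise_sd: float = 0.01):
    """Draw one (proportion vector, cell-count vector) pair.

    Resamples (up to a bounded number of attempts) whenever any type
    would receive zero cells, so every type is represented.
    """
    rng = rng or np.random.default_rng()
    n_types = len(cell_types)
    if total_cells < n_types:
        raise ValueError(
            f"total_cells={total_cells} cannot represent {n_types} types")
    if scheme == "realistic":
        if base is None:
            raise ValueError("realistic scheme requires base proportions")
        base = np.asarray(base, dtype=float)
        if base.sum() <= 0 or np.any(base < 0):
            raise ValueError("base proportions must be non-negative, sum > 0")
        base = base / base.sum()
    elif scheme != "random":
        raise ValueError(f"unknown scheme {scheme!r}")

    for _ in range(_MAX_RESAMPLE):
        if scheme == "random":
            p = rng.dirichlet(np.ones(n_types))
        else:
            p = base + rng.normal(0.0, noise_sd, size=n_types)
            p = np.clip(p, 0.0, None)
            if p.sum() <= 0:
                continue
            p = p / p.sum()
        counts = _allocate_counts(p, total_cells)
        if np.all(counts > 0):
            return counts / total_cells, counts
    raise RuntimeError(
        f"failed to draw all-positive cell counts after {_MAX_RESAMPLE} tries")


def build_pseudobulks(source: LabeledCounts, n_random: int = 500,
                      n_realistic: int = 500, total_cells: int = 1000,
                      noise_sd: float = 0.05, seed: int = 0) -> PseudobulkSet:
    """Build a PseudobulkSet from a single-modality LabeledCounts source."""
    if len(set(source.modality)) > 1:
        raise ValueError("pseudobulk source must use a single modality")
    rng = np.random.default_rng(seed)
    cell_types = sorted(set(source.cell_type))
    type_idx = {t: np.flatnonzero(source.cell_type == t) for t in cell_types}
    for t, idx in type_idx.items():
        if len(idx) == 0:
            raise ValueError(f"cell type {t!r} absent from source")
    base = np.array([len(type_idx[t]) for t in cell_types], dtype=float)
    base = base / base.sum()

    dense = source.dense().astype(float)
    n_total = n_random + n_realistic
    schemes = np.array(["random"] * n_random + ["realistic"] * n_realistic,
                       dtype=object)
    bulk_rows = np.empty((n_total, source.n_genes))
    props = np.empty((n_total, len(cell_types)))
    counts_mat = np.empty((n_total, len(cell_types)), dtype=int)
    manifest = []
    for i, scheme in enumerate(schemes):
        p, counts = sample_proportions(
            scheme, cell_types, total_cells=total_cells,
            base=base if scheme == "realistic" else None, rng=rng)
        row = np.zeros(source.n_genes)
        entry = {}
        for t, k in zip(cell_types, counts):
            pool = type_idx[t]
            replace = len(pool) < k
            if replace:
                logger.debug("type %s: sampling %d of %d with replacement",
                             t, k, len(pool))
            chosen = rng.choice(pool, size=k, replace=replace)
            row += dense[chosen].sum(axis=0)
            entry[t] = chosen
        if noise_sd > 0:
            row = row + rng.normal(0.0, noise_sd, size=row.shape)
        bulk_rows[i] = np.clip(row, 0.0, None)
        props[i] = p
        counts_mat[i] = counts
        manifest.append(entry)

    bulk = BulkMatrix(
        values=bulk_rows,
        gene_ids=source.gene_ids.copy(),
        sample_ids=np.array([f"pb{i:04d}" for i in range(n_total)],
                            dtype=object),
    )
    return PseudobulkSet(bulk=bulk, proportions=props, cell_counts=counts_mat,
                         cell_types=cell_types, scheme=schemes,
                         manifest=manifest, seed=seed,
                         total_cells=total_cells)


def rebuild_from_manifest(source: LabeledCounts,
                          pbs: PseudobulkSet) -> np.ndarray:
    """Re-sum the recorded cell indices; equals pbs.bulk when noise_sd=0."""
    dense = source.dense().astype(float)
    out = np.zeros((len(pbs.manifest), source.n_genes))
    for i, entry in enumerate(pbs.manifest):
        for idx in entry.values():
            out[i] += dense[np.asarray(idx)].sum(axis=0)
    return out
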