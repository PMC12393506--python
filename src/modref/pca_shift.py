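"""PCA neighbour-based shift of nucleus profiles toward the cell modality.

The training pool (scRNA cells plus nucleus cells of overlapping types)
is log1p-transformed, standardized per gene and decomposed by PCA,
keeping the minimum number of components that capture at least 75% of
total variance. Each overlapping nucleus cell stores a shift vector
pointing from its own projection to the centroid of the scRNA
projections. A missing-type nucleus cell is projected, its k = 10
nearest overlapping nucleus neighbours (Euclidean in component space)
are found, and the mean of their stored shift vectors is added before
inverse-projecting back to expression space (un-standardize, expm1, clip
at zero) and rescaling every cell to the target library size L — the
median per-cell total of the scRNA training cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import LabeledCounts

logger = logging.getLogger(__name__)


@dataclass
class PCAShiftModel:
    gene_ids: np.ndarray
    mean_: np.ndarray             # per-gene log1p mean over the training pool
    scale_: np.ndarray            # per-gene sd, floored at 1 for zero variance
    components_: np.ndarray       # (d, n_genes)
    pca_mean_: np.ndarray         # PCA centering vector in scaled space
    explained_variance_ratio_: np.ndarray
    centroid: np.ndarray          # global scRNA centroid in component space
    train_projections: np.ndarray # overlapping snRNA cells, component space
    train_shifts: np.ndarray      # per training cell: centroid - projection
    k: int
    target_library_size: float
    shift_mode: str = "stored"    # or "displacement"
    centroid_mode: str = "per_type"  # or "global"

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (np.log1p(values) - self.mean_) / self.scale_

    def project(self, values: np.ndarray) -> np.ndarray:
        return (self.standardize(values) - self.pca_mean_) @ self.components_.T

    def inverse(self, z: np.ndarray) -> np.ndarray:
        scaled = z @ self.components_ + self.pca_mean_
        logs = scaled * self.scale_ + self.mean_
        return np.clip(np.expm1(logs), 0.0, None)


_ARRAY_FIELDS = ("gene_ids", "mean_", "scale_", "components_", "pca_mean_",
                 "explained_variance_ratio_", "centroid",
                 "train_projections", "train_shifts")


def save_pca_shift(model: PCAShiftModel, path: str) -> None:
    """Serialize the model: arrays as .npz plus a JSON manifest."""
    import json
    import os
    os.makedirs(path, exist_ok=True)
    arrays = {k: np.asarray(getattr(model, k)) for k in _ARRAY_FIELDS}
    arrays["gene_ids"] = arrays["gene_ids"].astype(str)
    np.savez(os.path.join(path, "arrays.npz"), **arrays)
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump({"k": model.k,
                   "target_library_size": model.target_library_size,
                   "shift_mode": model.shift_mode,
                   "centroid_mode": model.centroid_mode,
                   "n_components": model.n_components}, fh, indent=1)


def load_pca_shift(path: str) -> PCAShiftModel:
    import json
    import os
    with np.load(os.path.join(path, "arrays.npz"), allow_pickle=False) as z:
        arrays = {k: z[k] for k in _ARRAY_FIELDS}
    arrays["gene_ids"] = arrays["gene_ids"].astype(object)
    with open(os.path.join(path, "manifest.json")) as fh:
        meta = json.load(fh)
    return PCAShiftModel(**arrays, k=meta["k"],
                         target_library_size=meta["target_library_size"],
                         shift_mode=meta["shift_mode"],
                         centroid_mode=meta["centroid_mode"])


def fit_pca_shift(sc_train: LabeledCounts, sn_overlap: LabeledCounts,
                  var_threshold: float = 0.75, k: int = 10,
                  library_stat: str = "median",
                  shift_mode: str = "stored",
                  centroid_mode: str = "per_type") -> PCAShiftModel:
    """Fit scaler, PCA, scRNA centroid(s) and per-cell shift vectors.

    ``centroid_mode="per_type"`` (default) stores, for every overlapping
    nucleus cell, the vector from that cell to its own type's scRNA
    centroid — the local modality correction in the MNN-shift lineage.
    ``"global"`` uses the centroid of all scRNA training cells instead;
    that reading mixes type identity into the shifts (each shift then
    also points away from the cell's own type toward the average of the
    training types) and degrades missing-type imputation accordingly.
    """
    if not np.array_equal(sc_train.gene_ids, sn_overlap.gene_ids):
        raise ValueError("inputs must be gene-aligned")
    sc = sc_train.dense().astype(float)
    sn = sn_overlap.dense().astype(float)
    pool = np.vstack([sc, sn])
    logp = np.log1p(pool)
    mean = logp.mean(axis=0)
    sd = logp.std(axis=0, ddof=0)
    zero_var = sd == 0
    if zero_var.all():
        raise ValueError("all genes have zero variance in the training pool")
    sd = np.where(zero_var, 1.0, sd)  # floor avoids division blow-ups
    scaled = (logp - mean) / sd

    pca = PCA(svd_solver="full", random_state=0)
    pca.fit(scaled)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, var_threshold) + 1)
    d = min(d, len(cum))
    if pool.shape[0] < d:
        raise ValueError(f"need at least {d} training cells")
    components = pca.components_[:d]
    evr = pca.explained_variance_ratio_[:d]

    proj = (scaled - pca.mean_) @ components.T
    proj_sc = proj[: sc.shape[0]]
    proj_sn = proj[sc.shape[0]:]
    centroid = proj_sc.mean(axis=0)
    if centroid_mode == "per_type":
        shifts = np.empty_like(proj_sn)
        for t in np.unique(sn_overlap.cell_type):
            sc_mask = sc_train.cell_type == t
            sn_mask = sn_overlap.cell_type == t
            if not sc_mask.any():
                raise ValueError(
                    f"overlap type {t!r} has no scRNA training cells")
            shifts[sn_mask] = (proj_sc[sc_mask].mean(axis=0)[None, :]
                               - proj_sn[sn_mask])
    elif centroid_mode == "global":
        shifts = centroid[None, :] - proj_sn
    else:
        raise ValueError(f"unknown centroid mode {centroid_mode!r}")

    lib = sc.sum(axis=1)
    L = float(np.median(lib) if library_stat == "median" else lib.mean())
    return PCAShiftModel(
        gene_ids=sc_train.gene_ids.copy(), mean_=mean, scale_=sd,
        components_=components, pca_mean_=pca.mean_,
        explained_variance_ratio_=evr, centroid=centroid,
        train_projections=proj_sn, train_shifts=shifts, k=k,
        target_library_size=L, shift_mode=shift_mode,
        centroid_mode=centroid_mode,
    )


def knn_mean_shift(query: np.ndarray, train_proj: np.ndarray,
                   train_shifts: np.ndarray, k: int,
                   mode: str = "stored") -> np.ndarray:
    """Mean shift of the k nearest training cells, per query row.

    ``stored`` averages the neighbours' stored shift vectors (each points
    at the scRNA centroid); ``displacement`` averages the query→neighbour
    displacement instead — kept as a sensitivity-check alternative.
    """
    n_train = train_proj.shape[0]
    if n_train == 0:
        raise ValueError("no training cells to search")
    if k > n_train:
        logger.warning("k=%d lowered to %d available training cells",
                       k, n_train)
        k = n_train
    d2 = ((query[:, None, :] - train_proj[None, :, :]) ** 2).sum(axis=2)
    # stable argsort breaks distance ties by training index order
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    if mode == "stored":
        return train_shifts[nn].mean(axis=1)
    elif mode == "displacement":
        return (train_proj[nn] - query[:, None, :]).mean(axis=1)
    raise ValueError(f"unknown shift mode {mode!r}")


def rescale_rows(values: np.ndarray, target: float) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cannot rescale a zero-total cell")
    return values * (target / totals)


def apply_pca_shift(model: PCAShiftModel,
                    sn_missing: LabeledCounts) -> LabeledCounts:
    """Shift missing-type nucleus cells toward the cell modality."""
    if not np.array_equal(model.gene_ids, sn_missing.gene_ids):
        raise ValueError("input not gene-aligned to the model")
    x = sn_missing.dense().astype(float)
    z = model.project(x)
    shift = knn_mean_shift(z, model.train_projections, model.train_shifts,
                           model.k, model.shift_mode)
    shifted = model.inverse(z + shift)
    out = rescale_rows(shifted, model.target_library_size)
    return LabeledCounts(
        values=out, gene_ids=sn_missing.gene_ids.copy(),
        cell_type=sn_missing.cell_type.copy(),
        modality=sn_missing.modality.copy(),
        donor=sn_missing.donor.copy(),
        dataset_tag=sn_missing.dataset_tag + "_pca_shift",
    )
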