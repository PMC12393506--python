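"""Reference-panel assembly: controls, raw appends, gene pruning and the
three transformation algorithms, under the held-out protocol.

Each variant builds one deconvolution reference. Controls take every
cell from a single modality. The held-out variants keep all scRNA cells
except one type and re-supply that type from snRNA — raw, gene-pruned,
or transformed (PCA neighbour shift, VAE latent shift, conditional VAE
label switch). Per-type cell counts are equalized across variants so
that performance differences reflect the transformation, not reference
size. For transform variants, any model is (re)fitted on a training
pool that provably excludes the held-out type, and that pool is recorded
in the panel's training manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import LabeledCounts, align_genes
from .degenes import GeneSetCatalog, prune_genes
from .pca_shift import fit_pca_shift, apply_pca_shift
from .vae import (VAEConfig, apply_conditional, apply_latent_shift, fit_vae,
                  _median_library)

logger = logging.getLogger(__name__)

#: canonical variant key -> (display name, cells, removal, transform)
VARIANTS = {
    "pos_ctrl":      ("scRNA All (PosCtrl)", "sc_all", None, None),
    "neg_ctrl":      ("snRNA All (NegCtrl)", "sn_all", None, None),
    "sn_all_deg_int": ("snRNA All (-DEG Int.)", "sn_all", "intersection", None),
    "sn_raw":        ("snRNA", "mixed", None, None),
    "sn_deg":        ("snRNA -DEG", "mixed", "dataset_union", None),
    "pca":           ("PCA", "mixed", None, "pca"),
    "pca_deg":       ("PCA -DEG", "mixed", "dataset_union", "pca"),
    "scvi_ls":       ("scVILS", "mixed", None, "scvi_ls"),
    "scvi_ls_deg":   ("scVILS -DEG", "mixed", "dataset_union", "scvi_ls"),
    "scvi_cond":     ("scVIcond", "mixed", None, "scvi_cond"),
    "scvi_cond_deg": ("scVIcond -DEG", "mixed", "dataset_union", "scvi_cond"),
    "deg_int":       ("-DEG Int.", "mixed", "intersection_minus_held", None),
    "deg_other":     ("-DEG Other Datasets", "mixed", "other_datasets", None),
    "random_genes":  ("-Random Genes", "mixed", "random_matched", None),
}


@dataclass
class TransformSpec:
    """One reference variant: which cells, which genes, which transform."""

    variant: str
    held_out: object = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(VARIANTS)}")

    @property
    def display_name(self) -> str:
        return VARIANTS[self.variant][0]

    @property
    def cell_source(self) -> str:
        return VARIANTS[self.variant][1]

    @property
    def removal(self):
        return VARIANTS[self.variant][2]

    @property
    def transform(self):
        return VARIANTS[self.variant][3]

    @property
    def needs_held_out(self) -> bool:
        return self.cell_source == "mixed"


@dataclass
class ReferencePanel:
    """Cells (or signatures) + gene set backing one deconvolution run."""

    cells: LabeledCounts
    variant: str
    held_out: object = None
    removed_genes: frozenset = frozenset()
    training_manifest: dict = field(default_factory=dict)
    signature: np.ndarray | None = None

    @property
    def gene_ids(self) -> np.ndarray:
        return self.cells.gene_ids

    @property
    def cell_types(self) -> list:
        return sorted(set(self.cells.cell_type))


def _removal_set(spec: TransformSpec, catalog: GeneSetCatalog | None,
                 dataset: str) -> set:
    if spec.removal is None:
        return set()
    if catalog is None:
        raise ValueError(f"variant {spec.variant!r} needs a gene-set catalog")
    if spec.removal == "dataset_union":
        return set(catalog.per_dataset_union[dataset])
    if spec.removal == "intersection":
        return set(catalog.intersection_across_datasets)
    if spec.removal == "intersection_minus_held":
        inter = set(catalog.intersection_across_datasets)
        own = catalog.per_dataset_per_type.get((dataset, spec.held_out), set())
        return inter - set(own)
    if spec.removal == "other_datasets":
        return set(catalog.other_datasets_union[dataset])
    if spec.removal == "random_matched":
        return set(catalog.random_matched[dataset])
    raise ValueError(f"unhandled removal kind {spec.removal!r}")


def _equalized_counts(sc: LabeledCounts, sn: LabeledCounts) -> dict:
    """Per-type count shared by every variant: the smaller pool size for
    types present in both modalities, the available size otherwise."""
    ca, cb = sc.type_counts(), sn.type_counts()
    out = {}
    for t in sorted(set(ca) | set(cb)):
        if t in ca and t in cb:
            out[t] = min(ca[t], cb[t])
        else:
            out[t] = ca.get(t, cb.get(t, 0))
    return out


def _take(lc: LabeledCounts, ctype, n: int, rng) -> np.ndarray:
    pool = np.flatnonzero(lc.cell_type == ctype)
    if len(pool) < n:
        raise ValueError(f"type {ctype!r}: requested {n} of {len(pool)} cells")
    return np.sort(rng.choice(pool, size=n, replace=False))


def _concat(parts: list) -> LabeledCounts:
    first = parts[0]
    return LabeledCounts(
        values=np.vstack([p.dense().astype(float) for p in parts]),
        gene_ids=first.gene_ids.copy(),
        cell_type=np.concatenate([p.cell_type for p in parts]),
        modality=np.concatenate([p.modality for p in parts]),
        donor=np.concatenate([p.donor for p in parts]),
        dataset_tag=first.dataset_tag,
    )


def assemble_reference(spec: TransformSpec, sc: LabeledCounts,
                       sn: LabeledCounts, catalog: GeneSetCatalog = None,
                       dataset: str = "", models: dict = None,
                       seed: int = 0, vae_config: VAEConfig = None,
                       var_threshold: float = 0.75, k: int = 10
                       ) -> ReferencePanel:
    """Build one reference panel for a variant.

    ``models`` may pre-supply fitted models keyed by the variant name;
    otherwise any needed model is fitted here on the pruned gene space,
    excluding the held-out type from the training pool.
    """
    held = spec.held_out
    if spec.needs_held_out:
        if held is None:
            raise ValueError(f"variant {spec.variant!r} requires a held-out type")
        if held not in set(sn.cell_type):
            raise ValueError(f"held-out type {held!r} absent from snRNA data")
    sc, sn = align_genes(sc, sn)
    remove = _removal_set(spec, catalog, dataset)
    if remove:
        sc = prune_genes(sc, remove)
        sn = prune_genes(sn, remove)

    rng = np.random.default_rng(seed)
    counts = _equalized_counts(sc, sn)
    manifest = {"variant": spec.variant, "held_out": held, "seed": seed,
                "removed_genes": len(remove)}

    if spec.cell_source == "sc_all":
        idx = np.concatenate([_take(sc, t, n, rng) for t, n in counts.items()
                              if t in set(sc.cell_type)])
        cells = sc.subset_cells(idx)
    elif spec.cell_source == "sn_all":
        idx = np.concatenate([_take(sn, t, n, rng) for t, n in counts.items()
                              if t in set(sn.cell_type)])
        cells = sn.subset_cells(idx)
    else:  # mixed: scRNA for everything but the held-out type
        sc_idx = np.concatenate([_take(sc, t, n, rng)
                                 for t, n in counts.items()
                                 if t != held and t in set(sc.cell_type)])
        sc_part = sc.subset_cells(sc_idx)
        sn_idx = _take(sn, held, counts[held], rng)
        sn_part = sn.subset_cells(sn_idx)
        if spec.transform is not None:
            sn_part = _transform_held_out(
                spec, sc_part, sn, sn_part, held, counts, rng, models,
                seed, vae_config, var_threshold, k, manifest)
        cells = _concat([sc_part, sn_part])

    return ReferencePanel(cells=cells, variant=spec.variant, held_out=held,
                          removed_genes=frozenset(remove),
                          training_manifest=manifest)


def _transform_held_out(spec, sc_part, sn, sn_part, held, counts, rng,
                        models, seed, vae_config, var_threshold, k,
                        manifest):
    """Fit (or fetch) the variant's model and transform the held-out cells."""
    overlap_types = [t for t in counts
                     if t != held and t in set(sn.cell_type)]
    ov_idx = np.concatenate([_take(sn, t, counts[t], rng)
                             for t in overlap_types]) if overlap_types else \
        np.array([], dtype=int)
    sn_overlap = sn.subset_cells(ov_idx) if len(ov_idx) else None
    manifest["training_types"] = sorted(set(sc_part.cell_type))
    models = models or {}

    if spec.transform == "pca":
        if sn_overlap is None:
            raise ValueError("PCA shift needs overlapping snRNA cell types")
        model = models.get(spec.variant)
        if model is None:
            model = fit_pca_shift(sc_part, sn_overlap,
                                  var_threshold=var_threshold, k=k)
        return apply_pca_shift(model, sn_part)

    train_pool = _concat([sc_part, sn_overlap]) if sn_overlap is not None \
        else sc_part
    assert held not in set(train_pool.cell_type)
    if spec.transform == "scvi_ls":
        if sn_overlap is None:
            raise ValueError("latent shift needs overlapping snRNA cell types")
        model = models.get(spec.variant)
        if model is None:
            model = fit_vae(train_pool, conditional=False, config=vae_config,
                            seed=seed, held_out=held)
        return apply_latent_shift(model, sn_overlap, sn_part, sc_part, k=k)
    if spec.transform == "scvi_cond":
        model = models.get(spec.variant)
        if model is None:
            model = fit_vae(train_pool, conditional=True, config=vae_config,
                            seed=seed, held_out=held)
        return apply_conditional(model, sn_part,
                                 target_library=_median_library(sc_part))
    raise ValueError(f"unhandled transform {spec.transform!r}")
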