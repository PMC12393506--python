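"""Cross-modality differential expression and gene-removal catalogs.

Cells of each (cell type, modality) stratum are summed into 10-cell
aggregates (pseudo-replicates) and the nucleus-vs-cell contrast is tested
per gene with a negative-binomial Wald test: median-of-ratios size
factors, gene-wise moment dispersion with a small floor, per-group NB
mean MLE by Newton iteration, and a Wald statistic on the log fold
change. Benjamini-Hochberg adjustment is applied within each (dataset,
cell type) test; genes at padj < 0.01 are called DE.

The engine is pluggable: ``de_test(..., engine=fn)`` accepts any callable
with the same signature, so a DESeq2-compatible implementation can be
substituted.

The catalog assembles every gene-removal set used when building
references: per-dataset unions of per-type DEG lists (optionally
excluding a held-out type), the intersection of the per-dataset unions
across datasets, leave-one-dataset-out unions, and size-matched random
control sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import BulkMatrix, LabeledCounts

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class AggregateMatrix:
    """Summed pseudo-replicates of ``group_size`` distinct cells each."""

    values: np.ndarray            # (n_aggregates, n_genes) int
    gene_ids: np.ndarray
    cell_type: np.ndarray
    modality: np.ndarray
    replicate_index: np.ndarray
    group_size: int
    membership: list              # per-aggregate source cell indices
    low_replicate_strata: list = field(default_factory=list)


@dataclass
class DEResult:
    """Per-gene nucleus-vs-cell contrast for one cell type."""

    gene_ids: np.ndarray
    log2_fold_change: np.ndarray  # nucleus vs cell
    pvalue: np.ndarray            # NaN for untested (all-zero) genes
    padj: np.ndarray

    def significant_genes(self, alpha: float = 0.01) -> set:
        mask = np.isfinite(self.padj) & (self.padj < alpha)
        return set(self.gene_ids[mask].tolist())


@dataclass
class GeneSetCatalog:
    """All gene-removal sets derived from the per-type DE results."""

    per_dataset_per_type: dict        # (dataset, type) -> set
    per_dataset_union: dict           # dataset -> set (held-out excluded)
    intersection_across_datasets: set
    other_datasets_union: dict        # dataset -> union over the others
    random_matched: dict              # dataset -> size-matched random set
    held_out: object
    random_seed: int

    def export(self, path: str) -> None:
        import json
        import os
        os.makedirs(path, exist_ok=True)
        def _dump(name, genes):
            with open(os.path.join(path, f"{name}.txt"), "w") as fh:
                fh.write("\n".join(sorted(genes)) + "\n")
        for ds, genes in self.per_dataset_union.items():
            _dump(f"deg_union_{ds}", genes)
        _dump("deg_intersection", self.intersection_across_datasets)
        for ds, genes in self.other_datasets_union.items():
            _dump(f"deg_other_{ds}", genes)
        for ds, genes in self.random_matched.items():
            _dump(f"random_matched_{ds}", genes)
        with open(os.path.join(path, "catalog.json"), "w") as fh:
            json.dump({
                "datasets": sorted(self.per_dataset_union),
                "held_out": self.held_out,
                "random_seed": self.random_seed,
                "sizes": {ds: len(g)
                          for ds, g in self.per_dataset_union.items()},
                "intersection_size": len(self.intersection_across_datasets),
            }, fh, indent=1)


def make_aggregates(lc: LabeledCounts, group_size: int = 10,
                    seed: int = 0) -> AggregateMatrix:
    """Shuffle each (type, modality) stratum into non-overlapping
    ``group_size``-cell groups and sum them; remainder cells are dropped."""
    dense = lc.dense()
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("aggregation requires integer counts")
    dense = dense.astype(np.int64)
    rng = np.random.default_rng(seed)
    rows, types, mods, reps, members = [], [], [], [], []
    low = []
    strata = sorted(set(zip(lc.cell_type, lc.modality)))
    for ctype, mod in strata:
        idx = np.flatnonzero((lc.cell_type == ctype) & (lc.modality == mod))
        perm = rng.permutation(idx)
        n_groups = len(perm) // group_size
        if n_groups < 3:
            low.append((ctype, mod, n_groups))
        for g in range(n_groups):
            block = perm[g * group_size:(g + 1) * group_size]
            rows.append(dense[block].sum(axis=0))
            types.append(ctype)
            mods.append(mod)
            reps.append(g)
            members.append(block)
    if low:
        logger.warning("strata with < 3 aggregates: %s", low)
    return AggregateMatrix(
        values=np.array(rows, dtype=np.int64),
        gene_ids=lc.gene_ids.copy(),
        cell_type=np.array(types, dtype=object),
        modality=np.array(mods, dtype=object),
        replicate_index=np.array(reps, dtype=int),
        group_size=group_size,
        membership=members,
        low_replicate_strata=low,
    )


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs propagate untouched."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    m = len(pm)
    if m == 0:
        return out
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors; falls back to library-size ratios when no
    gene is expressed in every sample."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("aggregate with all-zero counts")
    everywhere = np.all(counts > 0, axis=0)
    if not everywhere.any():
        sf = lib / np.exp(np.mean(np.log(lib)))
        return sf
    logc = np.log(counts[:, everywhere])
    log_geomean = logc.mean(axis=0)
    sf = np.exp(np.median(logc - log_geomean[None, :], axis=1))
    return sf


def _nb_group_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
                   n_iter: int = 30):
    """Vectorized per-gene NB mean MLE for one group with known size
    factors and gene-wise dispersion alpha (var = mu + alpha mu^2).

    Returns (mean m, Fisher information of log m at the optimum)."""
    # y: (n_samples, n_genes); sf: (n_samples,); alpha: (n_genes,)
    qbar = (y / sf[:, None]).mean(axis=0)
    m = np.maximum(qbar, 1e-8)
    beta = np.log(m)
    for _ in range(n_iter):
        mu = sf[:, None] * np.exp(beta)[None, :]
        denom = 1.0 + alpha[None, :] * mu
        score = ((y - mu) / denom).sum(axis=0)
        info = (mu / denom).sum(axis=0)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = np.clip(beta + step, np.log(1e-10), 50.0)
    mu = sf[:, None] * np.exp(beta)[None, :]
    denom = 1.0 + alpha[None, :] * mu
    info = (mu / denom).sum(axis=0)
    return np.exp(beta), np.maximum(info, 1e-12)


def nb_wald_engine(counts: np.ndarray, is_nucleus: np.ndarray):
    """Default DE engine: NB Wald test of nucleus vs cell.

    Returns (log2fc, pvalue) arrays over genes; genes with zero counts
    everywhere get NaN in both.
    """
    counts = np.asarray(counts, dtype=float)
    is_nucleus = np.asarray(is_nucleus, dtype=bool)
    n_genes = counts.shape[1]
    if is_nucleus.sum() < 2 or (~is_nucleus).sum() < 2:
        raise ValueError("need >= 2 aggregates per modality")
    sf = median_of_ratios_size_factors(counts)
    tested = counts.sum(axis=0) > 0
    log2fc = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    y = counts[:, tested]
    q = y / sf[:, None]

    # gene-wise moment dispersion, pooled within groups, with floor
    inv_sf_mean = np.mean(1.0 / sf)
    groups = [~is_nucleus, is_nucleus]
    ss = np.zeros(y.shape[1])
    dof = 0
    for g in groups:
        qg = q[g]
        ss += qg.var(axis=0, ddof=1) * (g.sum() - 1)
        dof += g.sum() - 1
    var_within = ss / dof
    mu_hat = np.maximum(q.mean(axis=0), 1e-8)
    alpha = (var_within - mu_hat * inv_sf_mean) / mu_hat ** 2
    alpha = np.clip(alpha, DISPERSION_FLOOR, 1e4)

    m0, info0 = _nb_group_mean(y[~is_nucleus], sf[~is_nucleus], alpha)
    m1, info1 = _nb_group_mean(y[is_nucleus], sf[is_nucleus], alpha)
    lfc = np.log(m1) - np.log(m0)
    se = np.sqrt(1.0 / info0 + 1.0 / info1)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    log2fc[tested] = lfc / np.log(2.0)
    pval[tested] = p
    return log2fc, pval


def de_test(agg: AggregateMatrix, cell_type, engine=None) -> DEResult:
    """Nucleus-vs-cell differential expression for one cell type."""
    engine = engine or nb_wald_engine
    mask = agg.cell_type == cell_type
    if not mask.any():
        raise ValueError(f"cell type {cell_type!r} absent from aggregates")
    sub = agg.values[mask]
    mods = agg.modality[mask]
    present = set(mods)
    if present != {"cell", "nucleus"}:
        missing = {"cell", "nucleus"} - present
        raise ValueError(f"modality {sorted(missing)} absent for "
                         f"type {cell_type!r}")
    log2fc, pval = engine(sub, mods == "nucleus")
    padj = benjamini_hochberg(pval)
    return DEResult(gene_ids=agg.gene_ids.copy(), log2_fold_change=log2fc,
                    pvalue=pval, padj=padj)


def build_catalog(de_results: dict, datasets: list, gene_universe,
                  held_out=None, alpha: float = 0.01,
                  random_seed: int = 0) -> GeneSetCatalog:
    """Assemble all gene-removal sets from (dataset, cell_type)-keyed
    DEResults.

    ``held_out``, when given, excludes that cell type's own DEG list from
    every per-dataset union (references never prune based on the type
    they are trying to rescue).
    """
    for key in de_results:
        if key[0] not in datasets:
            raise ValueError(f"unknown dataset key {key[0]!r}")
    per_type = {key: res.significant_genes(alpha)
                for key, res in de_results.items()}
    per_dataset_union = {}
    for ds in datasets:
        union = set()
        for (d, t), genes in per_type.items():
            if d == ds and t != held_out:
                union |= genes
        per_dataset_union[ds] = union
    intersection = None
    for ds in datasets:
        intersection = (per_dataset_union[ds] if intersection is None
                        else intersection & per_dataset_union[ds])
    intersection = intersection or set()
    other = {ds: set().union(*(per_dataset_union[d] for d in datasets
                               if d != ds)) if len(datasets) > 1 else set()
             for ds in datasets}
    rng = np.random.default_rng(random_seed)
    universe = np.asarray(list(gene_universe), dtype=object)
    random_matched = {}
    for ds in datasets:
        k = len(per_dataset_union[ds])
        k = min(k, len(universe))
        random_matched[ds] = set(
            rng.choice(universe, size=k, replace=False).tolist())
    return GeneSetCatalog(
        per_dataset_per_type=per_type,
        per_dataset_union=per_dataset_union,
        intersection_across_datasets=intersection,
        other_datasets_union=other,
        random_matched=random_matched,
        held_out=held_out,
        random_seed=random_seed,
    )


def prune_genes(x, remove):
    """Drop ``remove`` genes from a LabeledCounts or BulkMatrix; order of
    the survivors is preserved and values are untouched."""
    remove = set(remove)
    keep = np.array([g not in remove for g in x.gene_ids])
    if not keep.any():
        raise ValueError("pruning would leave an empty gene set")
    return x.subset_genes(np.flatnonzero(keep))
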