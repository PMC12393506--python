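"""Synthetic paired scRNA/snRNA data with known modality effects.

The generator emulates the biological setting the package targets: the
two modalities share per-cell-type expression programs, but a fraction
of genes carries a systematic abundance shift in the nucleus modality
(nuclear transcripts are enriched for some genes and depleted for
others relative to whole cells, because cytoplasmic RNA is absent from
nuclei). Donor structure and variable library sizes are layered on top.

Cell identity lives on a shared low-dimensional manifold, as in real
tissues: expression means follow a log-linear factor model. Each cell
type t has an activity vector b_t over a set of expression programs
(one identity program per type plus shared modules); each gene g has a
loading row Λ_g; each cell draws its own activity a_i ~ N(b_t, σ_w² I),
so every program axis — including a held-out type's identity axis — is
visible as within-type covariation in the remaining types. Marker genes
are the genes strongly loaded on their type's identity program.

The per-cell NB mean for gene g is

    mu = library_factor · donor_factor · baseline_g
         · exp(Λ_g · a_i − σ_w²‖Λ_g‖²/2)
         · modality_effect(g)^(1 if nucleus else 0)

(the Gaussian correction keeps the per-type expectation at
baseline_g · exp(Λ_g · b_t)), and counts are negative binomial with a
single shared dispersion theta (variance = mu + mu²/theta).

Features of real data deliberately not modelled: doublets, ambient RNA,
UMI saturation, and tissue-specific DEG counts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .containers import BulkMatrix, LabeledCounts


@dataclass
class SyntheticConfig:
    """Knobs of the paired-modality generator; defaults give a small
    four-type tissue with a 10% modality-shifted gene fraction."""

    n_genes: int = 2000
    # (name, n cells in cell modality, n cells in nucleus modality);
    # abundances are skewed, as in real tissues — equal abundances would
    # make the empirical-proportion pseudobulk scheme degenerate
    cell_types: tuple = (
        ("typeA", 350, 350),
        ("typeB", 280, 280),
        ("typeC", 220, 220),
        ("typeD", 150, 150),
    )
    n_markers_per_type: int = 200
    marker_log2fc: float = 3.0
    modality_effect_fraction: float = 0.10
    modality_log2fc_range: tuple = (1.0, 2.0)
    # sd (log2) of the per-cell-type deviation around the shared effect,
    # applied to effect genes only: nuclear retention interacts with the
    # type's expression program, so per-type modality DEG profiles differ
    modality_type_interaction_log2sd: float = 0.5
    nb_dispersion: float = 10.0
    library_size_lognorm: tuple = (0.0, 0.3)
    n_donors: int = 3
    donor_effect_sd: float = 0.10
    # expression-manifold structure
    n_shared_programs: int = 6
    program_loading_sd: float = 0.4
    within_type_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.modality_effect_fraction <= 1.0:
            raise ValueError("modality_effect_fraction must lie in [0, 1]")
        lo, hi = self.modality_log2fc_range
        if lo > hi:
            raise ValueError("modality_log2fc_range must have lo <= hi")
        if self.n_genes <= 0 or self.n_markers_per_type < 0:
            raise ValueError("counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.donor_effect_sd < 0 or self.within_type_sd < 0:
            raise ValueError("effect sds must be >= 0")
        total = sum(nc + nn for _, nc, nn in self.cell_types)
        if total <= 0:
            raise ValueError("degenerate config: zero cells in total")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated tissue: what a perfect method would
    find, plus the factor-model internals needed to redraw new samples
    of the same tissue."""

    modality_effect: np.ndarray          # per-gene nucleus multiplier, 1 = none
    marker_genes: dict                   # type -> list of gene ids
    donor_effects: dict                  # donor -> per-gene multiplier vector
    base_mean: np.ndarray                # (n_types, n_genes) expected means
    cell_types: list
    gene_ids: np.ndarray
    baseline: np.ndarray = None          # per-gene baseline mean
    loadings: np.ndarray = None          # (n_genes, n_programs)
    type_activities: np.ndarray = None   # (n_types, n_programs)
    type_scale: np.ndarray = None        # per-type transcript-budget scaler
    modality_effect_by_type: np.ndarray = None  # (n_types, n_genes) multipliers

    @property
    def effect_gene_ids(self) -> np.ndarray:
        return self.gene_ids[self.modality_effect != 1.0]

    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        import pandas as pd
        pd.DataFrame({
            "gene_id": self.gene_ids,
            "modality_effect": self.modality_effect,
        }).to_csv(os.path.join(path, "modality_effect.tsv"), sep="\t",
                  index=False)
        with open(os.path.join(path, "truth.json"), "w") as fh:
            json.dump({
                "marker_genes": {k: list(v) for k, v in self.marker_genes.items()},
                "cell_types": list(self.cell_types),
                "donors": sorted(self.donor_effects),
            }, fh, indent=1)


def _build_manifold(cfg: SyntheticConfig, rng: np.random.Generator):
    """Baseline means, program loadings and per-type activities.

    Program axes: one identity axis per type followed by
    ``n_shared_programs`` shared modules. Markers carry a loading of
    marker_log2fc·ln2 on their type's identity axis, whose activity is 1
    for that type, so the marker mean boost is 2^marker_log2fc.
    """
    n_types = len(cfg.cell_types)
    n_prog = n_types + cfg.n_shared_programs
    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    loadings = rng.normal(0.0, cfg.program_loading_sd,
                          size=(cfg.n_genes, n_prog))
    markers = {}
    cursor = 0
    for t_idx, (name, _, _) in enumerate(cfg.cell_types):
        idx = np.arange(cursor, cursor + cfg.n_markers_per_type)
        idx = idx[idx < cfg.n_genes]
        loadings[idx, t_idx] = cfg.marker_log2fc * np.log(2.0)
        markers[name] = idx
        cursor += cfg.n_markers_per_type
    activities = np.zeros((n_types, n_prog))
    activities[:, :n_types] = np.eye(n_types)
    activities[:, n_types:] = rng.normal(0.0, 1.0,
                                         size=(n_types, cfg.n_shared_programs))
    # equalize per-type transcript budgets: cell-count proportions and
    # read-mass proportions then coincide, so deconvolution accuracy is
    # not confounded by RNA-content differences between types
    totals = (baseline[None, :] * np.exp(activities @ loadings.T)).sum(axis=1)
    type_scale = baseline.sum() / totals
    return baseline, loadings, activities, markers, type_scale


def generate_paired(config: SyntheticConfig, truth: SyntheticTruth = None,
                    donor_prefix: str = "donor"):
    """Generate matched scRNA and snRNA LabeledCounts plus the truth object.

    When ``truth`` is supplied, its expression programs and modality
    effects are reused and only new cells/donors are drawn — an
    independent sample of the same tissue, as needed when the reference
    and the pseudobulk source must not share donors.

    Cell types listed with zero cells in one modality are simply absent
    from that output (modelling dissociation-sensitive types that only
    nuclei capture). Same seed -> bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    type_names = [name for name, _, _ in config.cell_types]
    if truth is not None:
        if list(truth.cell_types) != type_names:
            raise ValueError("truth cell types do not match the config")
        gene_ids = truth.gene_ids
        baseline = truth.baseline
        loadings = truth.loadings
        activities = truth.type_activities
        marker_idx = {k: np.flatnonzero(np.isin(truth.gene_ids, v))
                      for k, v in truth.marker_genes.items()}
        effect = truth.modality_effect
        effect_by_type = truth.modality_effect_by_type
        type_scale = truth.type_scale
    else:
        (baseline, loadings, activities, marker_idx,
         type_scale) = _build_manifold(config, rng)
        gene_ids = np.array([f"g{i:05d}" for i in range(config.n_genes)],
                            dtype=object)
        # nucleus-vs-cell effect: random subset of genes, symmetric up/down
        n_eff = int(round(config.modality_effect_fraction * config.n_genes))
        effect = np.ones(config.n_genes)
        n_types_cfg = len(config.cell_types)
        effect_by_type = np.ones((n_types_cfg, config.n_genes))
        if n_eff > 0:
            # modality-shifted genes are biased toward high expressors:
            # nuclear enrichment (lncRNA, nascent) and cytoplasmic
            # depletion (ribosomal, mitochondrial) both concentrate in
            # abundant transcripts
            weights = baseline / baseline.sum()
            eff_idx = rng.choice(config.n_genes, size=n_eff, replace=False,
                                 p=weights)
            lo, hi = config.modality_log2fc_range
            mag = rng.uniform(lo, hi, size=n_eff)
            sign = rng.choice([-1.0, 1.0], size=n_eff)
            effect[eff_idx] = 2.0 ** (sign * mag)
            interaction = rng.normal(
                0.0, config.modality_type_interaction_log2sd,
                size=(n_types_cfg, n_eff))
            effect_by_type[:, eff_idx] = effect[eff_idx][None, :] \
                * 2.0 ** interaction

    # per-type expected means (within-type activity noise integrates out)
    base = type_scale[:, None] * baseline[None, :] * np.exp(
        activities @ loadings.T)

    donors = [f"{donor_prefix}{i}" for i in range(config.n_donors)]
    donor_effects = {
        d: np.exp(rng.normal(0.0, config.donor_effect_sd, size=config.n_genes))
        for d in donors
    }

    mu_lib, sd_lib = config.library_size_lognorm
    sigma_w = config.within_type_sd
    # Jensen correction so E[exp(Λ·a)] over a ~ N(b_t, σ_w² I) matches base
    jensen = np.exp(-0.5 * sigma_w ** 2 * (loadings ** 2).sum(axis=1))
    outputs = {}
    for modality, col in (("cell", 1), ("nucleus", 2)):
        blocks, labels, mods, dnrs = [], [], [], []
        for t_idx, spec_row in enumerate(config.cell_types):
            name, n_cells = spec_row[0], spec_row[col]
            if n_cells == 0:
                continue
            lib = rng.lognormal(mean=mu_lib, sigma=sd_lib, size=n_cells)
            donor_assign = rng.integers(0, config.n_donors, size=n_cells)
            act = activities[t_idx][None, :] + rng.normal(
                0.0, sigma_w, size=(n_cells, loadings.shape[1]))
            cell_factor = np.exp(act @ loadings.T) * jensen[None, :]
            mean_g = type_scale[t_idx] * baseline[None, :] * cell_factor
            if modality == "nucleus":
                mean_g = mean_g * effect_by_type[t_idx][None, :]
            donor_mat = np.stack([donor_effects[donors[d]]
                                  for d in donor_assign])
            mu = lib[:, None] * donor_mat * mean_g
            theta = config.nb_dispersion
            # NB as gamma-poisson mixture
            lam = rng.gamma(theta, mu / theta)
            counts = rng.poisson(lam)
            blocks.append(counts)
            labels.extend([name] * n_cells)
            mods.extend([modality] * n_cells)
            dnrs.extend([donors[d] for d in donor_assign])
        if not blocks:
            raise ValueError(f"no cells generated for modality {modality!r}")
        outputs[modality] = LabeledCounts(
            values=np.vstack(blocks).astype(np.int64),
            gene_ids=gene_ids,
            cell_type=np.array(labels, dtype=object),
            modality=np.array(mods, dtype=object),
            donor=np.array(dnrs, dtype=object),
            dataset_tag=f"synthetic_{modality}",
        )

    out_truth = SyntheticTruth(
        modality_effect=effect,
        marker_genes={k: gene_ids[v].tolist() for k, v in marker_idx.items()},
        donor_effects=donor_effects,
        base_mean=base,
        cell_types=type_names,
        gene_ids=gene_ids,
        baseline=baseline,
        loadings=loadings,
        type_activities=activities,
        type_scale=type_scale,
        modality_effect_by_type=effect_by_type,
    ) if truth is None else truth
    return outputs["cell"], outputs["nucleus"], out_truth


def generate_bulk_cohort(truth: SyntheticTruth, n_samples: int,
                         proportions=None, noise_sd: float = 0.1,
                         seed: int = 0, library_size: float = 1e6):
    """Simulate a bulk cohort from the cell-modality base means.

    Each sample is a proportion-weighted mixture of the per-type base
    means, scaled to a common library size, with multiplicative lognormal
    noise. Returns (BulkMatrix, true proportion matrix).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    n_types = len(truth.cell_types)
    if proportions is None:
        props = rng.dirichlet(np.ones(n_types), size=n_samples)
    else:
        props = np.atleast_2d(np.asarray(proportions, dtype=float))
        if props.shape != (n_samples, n_types):
            raise ValueError("proportions must be (n_samples, n_types)")
        rowsum = props.sum(axis=1, keepdims=True)
        if np.any(rowsum <= 0):
            raise ValueError("proportion rows must have positive sum")
        props = props / rowsum
    mix = props @ truth.base_mean
    mix = mix / mix.sum(axis=1, keepdims=True) * library_size
    if noise_sd > 0:
        mix = mix * rng.lognormal(0.0, noise_sd, size=mix.shape)
    bulk = BulkMatrix(
        values=mix,
        gene_ids=truth.gene_ids.copy(),
        sample_ids=np.array([f"bulk{i:04d}" for i in range(n_samples)],
                            dtype=object),
    )
    return bulk, props
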