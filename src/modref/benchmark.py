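"""One-call synthetic benchmark mirroring the held-out study design.

For a given seed the benchmark

1. draws a synthetic tissue (cell-type programs + modality-effect genes),
2. draws two independent samples of that tissue: one whose scRNA cells
   form the pseudobulks, and one providing the scRNA/snRNA reference
   pair (disjoint donors, same programs),
3. builds pseudobulks with known proportions,
4. computes the cross-modality DEG catalog on the reference pair,
5. assembles one reference per requested variant under the held-out
   protocol, deconvolves all pseudobulks with the built-in NNLS backend,
6. returns per-sample evaluation records for the three scenarios.

This is the engine behind the package's summary experiments; tests and
the reproduction script both call it rather than re-scripting the
stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .containers import LabeledCounts, align_genes
from .deconvolve import deconvolve
from .degenes import build_catalog, de_test, make_aggregates
from .evaluate import EvaluationRecord, score_removed, score_sample
from .pseudobulk import build_pseudobulks
from .reference import ReferencePanel, TransformSpec, assemble_reference
from .simulate import SyntheticConfig, generate_paired
from .vae import VAEConfig

logger = logging.getLogger(__name__)


def _combined(a: LabeledCounts, b: LabeledCounts) -> LabeledCounts:
    return LabeledCounts(
        values=np.vstack([a.dense(), b.dense()]),
        gene_ids=a.gene_ids.copy(),
        cell_type=np.concatenate([a.cell_type, b.cell_type]),
        modality=np.concatenate([a.modality, b.modality]),
        donor=np.concatenate([a.donor, b.donor]),
        dataset_tag=a.dataset_tag,
    )


@dataclass
class BenchmarkResult:
    records: list                     # EvaluationRecord per sample/scenario
    held_out: object
    truth: object
    catalog: object
    proportions_true: np.ndarray
    estimates: dict                   # variant -> DeconvolutionResult

    def mean_pearson(self, variant: str, scenario: str = "all") -> float:
        vals = [r.pearson for r in self.records
                if r.transform == variant and r.scenario == scenario
                and np.isfinite(r.pearson)]
        return float(np.mean(vals)) if vals else np.nan

    def pearson_values(self, variant: str, scenario: str = "all"):
        return np.array([r.pearson for r in self.records
                         if r.transform == variant
                         and r.scenario == scenario])

    def rmse_values(self, variant: str, scenario: str = "all"):
        return np.array([r.rmse for r in self.records
                         if r.transform == variant
                         and r.scenario == scenario])


def run_benchmark(seed: int,
                  variants=("pos_ctrl", "neg_ctrl", "sn_raw", "sn_deg"),
                  synthetic_config: SyntheticConfig = None,
                  n_random: int = 50, n_realistic: int = 50,
                  held_out: str = None, noise_sd: float = 0.05,
                  vae_config: VAEConfig = None,
                  dataset_name: str = "synthetic") -> BenchmarkResult:
    """Run the held-out benchmark for one seed; see the module docstring."""
    syn = synthetic_config or SyntheticConfig()
    cfg_truth = SyntheticConfig(**{**syn.__dict__,
                                   "seed": derive_seed(seed, "truth")})
    _, _, truth = generate_paired(cfg_truth)

    cfg_a = SyntheticConfig(**{**syn.__dict__,
                               "seed": derive_seed(seed, "pseudobulk_draw")})
    sc_pb, _, _ = generate_paired(cfg_a, truth=truth, donor_prefix="pbdonor")
    cfg_b = SyntheticConfig(**{**syn.__dict__,
                               "seed": derive_seed(seed, "reference_draw")})
    sc_ref, sn_ref, _ = generate_paired(cfg_b, truth=truth,
                                        donor_prefix="refdonor")

    held = held_out or sorted(set(sc_pb.cell_type))[0]
    pbs = build_pseudobulks(sc_pb, n_random=n_random,
                            n_realistic=n_realistic, noise_sd=noise_sd,
                            seed=derive_seed(seed, "pseudobulk"))

    needs_catalog = any(TransformSpec(v).removal is not None
                        for v in variants)
    catalog = None
    if needs_catalog:
        agg = make_aggregates(_combined(sc_ref, sn_ref),
                              seed=derive_seed(seed, "aggregates"))
        shared = sorted(set(sc_ref.cell_type) & set(sn_ref.cell_type))
        de = {(dataset_name, t): de_test(agg, t) for t in shared}
        catalog = build_catalog(de, [dataset_name],
                                gene_universe=sc_ref.gene_ids,
                                held_out=held,
                                random_seed=derive_seed(seed, "random_genes"))

    records = []
    estimates = {}
    types = sorted(set(pbs.cell_types))
    for variant in variants:
        spec_held = held if TransformSpec(variant).needs_held_out else None
        spec = TransformSpec(variant, held_out=spec_held)
        panel = assemble_reference(
            spec, sc_ref, sn_ref, catalog=catalog, dataset=dataset_name,
            seed=derive_seed(seed, "reference", variant),
            vae_config=vae_config)
        bulk, cells = align_genes(pbs.bulk, panel.cells)
        panel = ReferencePanel(cells=cells, variant=variant,
                               held_out=spec_held,
                               removed_genes=panel.removed_genes,
                               training_manifest=panel.training_manifest)
        result = deconvolve(bulk, panel)
        estimates[variant] = result
        est_order = [result.cell_types.index(t) for t in types]
        e_mat = result.proportions[:, est_order]
        t_mat = pbs.proportions
        held_idx = types.index(held) if spec_held is not None else None
        for i in range(t_mat.shape[0]):
            p, r = score_sample(t_mat[i], e_mat[i], "all")
            records.append(EvaluationRecord(dataset_name, variant, spec_held,
                                            "all", f"pb{i:04d}", p, r))
            if held_idx is not None:
                p, r = score_sample(t_mat[i], e_mat[i], "non_removed",
                                    held_out_index=held_idx)
                records.append(EvaluationRecord(dataset_name, variant,
                                                spec_held, "non_removed",
                                                f"pb{i:04d}", p, r))
        if held_idx is not None:
            p, r = score_removed(t_mat[:, held_idx], e_mat[:, held_idx])
            records.append(EvaluationRecord(dataset_name, variant, spec_held,
                                            "removed_only", "pooled", p, r))
    return BenchmarkResult(records=records, held_out=held, truth=truth,
                           catalog=catalog,
                           proportions_true=pbs.proportions,
                           estimates=estimates)
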