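"""End-to-end orchestration of the synthetic benchmark.

Stages (each writes its artifacts plus a JSON manifest with parameter
values, seeds and input-file hashes):

  simulate   -> paired scRNA/snRNA counts + ground truth
  pseudobulk -> mixtures with known proportions from the scRNA data
  deg        -> cross-modality DE per cell type and the gene-set catalog
  transform  -> one reference panel per requested variant (models
                trained here under the held-out protocol)
  deconvolve -> proportion estimates per panel
  evaluate   -> per-sample accuracy records for the three scenarios
  report     -> summary tables (mean + bootstrap CI per transform ×
                scenario) and composite scores

Rerunning a stage with identical inputs and seed reproduces its outputs
bit-exactly (the VAE stages too, since training is pure numpy under one
seeded generator).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._seeds import derive_seed
from .containers import align_genes, filter_min_cells
from .deconvolve import deconvolve
from .degenes import build_catalog, de_test, make_aggregates
from .evaluate import (EvaluationRecord, bootstrap_mean_ci, composite_scores,
                       records_to_frame, robustness_from_results,
                       score_removed, score_sample)
from .pseudobulk import build_pseudobulks
from .reference import TransformSpec, assemble_reference
from .simulate import SyntheticConfig, generate_paired
from .vae import VAEConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "pseudobulk", "deg", "transform", "deconvolve",
          "evaluate", "report")

DEFAULT_TRANSFORMS = ("pos_ctrl", "neg_ctrl", "sn_raw", "sn_deg", "pca",
                      "pca_deg")


@dataclasses.dataclass
class RunConfig:
    """All knobs of one benchmark run; numeric defaults follow the
    package's study conditions."""

    output_dir: str = "modref_run"
    master_seed: int = 0
    dataset_name: str = "synthetic"
    # synthetic data
    synthetic: dict = dataclasses.field(default_factory=dict)
    # pseudobulks
    n_random: int = 500
    n_realistic: int = 500
    total_cells: int = 1000
    noise_sd: float = 0.05
    # DE
    group_size: int = 10
    alpha: float = 0.01
    # transforms
    transforms: tuple = DEFAULT_TRANSFORMS
    held_out: object = None          # default: first cell type
    var_threshold: float = 0.75
    k_neighbors: int = 10
    latent_dim: int = 30
    patience: int = 10
    max_epochs: int = 100
    # deconvolution
    backend: str = "nnls"

    def __post_init__(self):
        if self.master_seed is None:
            raise ValueError("master_seed is mandatory")
        if not 0 < self.var_threshold <= 1:
            raise ValueError("var_threshold must lie in (0, 1]")
        if self.k_neighbors < 1 or self.latent_dim < 1 or self.patience < 1:
            raise ValueError("k_neighbors, latent_dim, patience must be >= 1")
        unknown = set(self.transforms) - set(
            __import__("modref.reference", fromlist=["VARIANTS"]).VARIANTS)
        if unknown:
            raise ValueError(f"unknown transform variants {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        data.update(overrides)
        if "transforms" in data:
            data["transforms"] = tuple(data["transforms"])
        return cls(**data)

    def vae_config(self) -> VAEConfig:
        return VAEConfig(n_latent=self.latent_dim, patience=self.patience,
                         max_epochs=self.max_epochs)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write_manifest(stage_dir: str, stage: str, config: RunConfig,
                    inputs: list, params: dict) -> None:
    manifest = {
        "stage": stage,
        "master_seed": config.master_seed,
        "params": params,
        "inputs": {p: _hash_file(p) for p in inputs if os.path.isfile(p)},
    }
    with open(os.path.join(stage_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _stage_dir(config: RunConfig, stage: str, create: bool = False) -> str:
    d = os.path.join(config.output_dir, stage)
    if create:
        os.makedirs(d, exist_ok=True)
    return d


def _require(path: str, stage: str, needed_by: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage {needed_by!r} needs {path}; run stage {stage!r} first")
    return path


def run_stage(stage: str, config: RunConfig):
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    return globals()[f"_stage_{stage}"](config)


def run_all(config: RunConfig):
    for stage in STAGES:
        run_stage(stage, config)


# ----------------------------------------------------------------------

def _stage_simulate(config: RunConfig):
    d = _stage_dir(config, "simulate", create=True)
    syn = dict(config.synthetic)
    if "cell_types" in syn:
        syn["cell_types"] = tuple(tuple(x) for x in syn["cell_types"])
    syn.setdefault("seed", derive_seed(config.master_seed, "simulate"))
    cfg = SyntheticConfig(**syn)
    sc, sn, truth = generate_paired(cfg)
    mio.write_counts(sc, os.path.join(d, "sc"))
    mio.write_counts(sn, os.path.join(d, "sn"))
    truth.save(os.path.join(d, "truth"))
    _write_manifest(d, "simulate", config, [], dataclasses.asdict(cfg))
    return sc, sn, truth


def _load_pair(config: RunConfig):
    d = _stage_dir(config, "simulate")
    _require(os.path.join(d, "sc"), "simulate", "downstream")
    sc = mio.read_counts(os.path.join(d, "sc"))
    sn = mio.read_counts(os.path.join(d, "sn"))
    sc, sn = filter_min_cells(sc, sn, min_cells=1)
    return align_genes(sc, sn)


def _stage_pseudobulk(config: RunConfig):
    sc, _ = _load_pair(config)
    d = _stage_dir(config, "pseudobulk", create=True)
    pbs = build_pseudobulks(
        sc, n_random=config.n_random, n_realistic=config.n_realistic,
        total_cells=config.total_cells, noise_sd=config.noise_sd,
        seed=derive_seed(config.master_seed, "pseudobulk"))
    pbs.save(os.path.join(d, "bulk.tsv"), os.path.join(d, "proportions.csv"),
             os.path.join(d, "manifest_cells.json"))
    _write_manifest(d, "pseudobulk", config,
                    [os.path.join(_stage_dir(config, "simulate"),
                                  "sc", "matrix.mtx")],
                    {"n_random": config.n_random,
                     "n_realistic": config.n_realistic,
                     "total_cells": config.total_cells,
                     "noise_sd": config.noise_sd})
    return pbs


def _stage_deg(config: RunConfig):
    sc, sn = _load_pair(config)
    d = _stage_dir(config, "deg", create=True)
    from .containers import LabeledCounts
    combined = LabeledCounts(
        values=np.vstack([sc.dense(), sn.dense()]),
        gene_ids=sc.gene_ids.copy(),
        cell_type=np.concatenate([sc.cell_type, sn.cell_type]),
        modality=np.concatenate([sc.modality, sn.modality]),
        donor=np.concatenate([sc.donor, sn.donor]),
        dataset_tag=config.dataset_name,
    )
    agg = make_aggregates(combined, group_size=config.group_size,
                          seed=derive_seed(config.master_seed, "deg", "agg"))
    shared_types = sorted(set(sc.cell_type) & set(sn.cell_type))
    results = {}
    for t in shared_types:
        results[(config.dataset_name, t)] = de_test(agg, t)
    catalog = build_catalog(
        results, [config.dataset_name], gene_universe=sc.gene_ids,
        held_out=config.held_out, alpha=config.alpha,
        random_seed=derive_seed(config.master_seed, "deg", "random"))
    catalog.export(d)
    _write_manifest(d, "deg", config, [],
                    {"group_size": config.group_size, "alpha": config.alpha,
                     "held_out": config.held_out})
    return catalog


def _stage_transform(config: RunConfig):
    sc, sn = _load_pair(config)
    held = config.held_out or sorted(set(sc.cell_type))[0]
    _require(os.path.join(_stage_dir(config, "deg"), "catalog.json"),
             "deg", "transform")
    needs_catalog = any(
        TransformSpec(v, held_out=held if TransformSpec(v).needs_held_out
                      else None).removal is not None
        for v in config.transforms)
    catalog = None
    if needs_catalog:
        cfg2 = dataclasses.replace(config, held_out=held)
        catalog = _stage_deg(cfg2)
    d = _stage_dir(config, "transform", create=True)
    panels = {}
    for variant in config.transforms:
        spec = TransformSpec(variant,
                             held_out=held if TransformSpec(variant).needs_held_out
                             else None)
        panel = assemble_reference(
            spec, sc, sn, catalog=catalog, dataset=config.dataset_name,
            seed=derive_seed(config.master_seed, "transform", variant),
            vae_config=config.vae_config(),
            var_threshold=config.var_threshold, k=config.k_neighbors)
        pdir = os.path.join(d, variant)
        mio.write_counts(panel.cells, pdir, format="dense")
        with open(os.path.join(pdir, "panel.json"), "w") as fh:
            json.dump({"variant": variant, "held_out": panel.held_out,
                       "n_removed_genes": len(panel.removed_genes),
                       "manifest": panel.training_manifest}, fh,
                      indent=1, default=str)
        panels[variant] = panel
    _write_manifest(d, "transform", config, [],
                    {"transforms": list(config.transforms), "held_out": held})
    return panels


def _stage_deconvolve(config: RunConfig):
    d_pb = _stage_dir(config, "pseudobulk")
    _require(os.path.join(d_pb, "bulk.tsv"), "pseudobulk", "deconvolve")
    _require(_stage_dir(config, "transform"), "transform", "deconvolve")
    bulk = mio.read_bulk(os.path.join(d_pb, "bulk.tsv"))
    d = _stage_dir(config, "deconvolve", create=True)
    results = {}
    tdir = _stage_dir(config, "transform")
    for variant in config.transforms:
        pdir = os.path.join(tdir, variant)
        _require(os.path.join(pdir, "panel.json"), "transform", "deconvolve")
        cells = mio.read_counts(pdir, format="dense")
        with open(os.path.join(pdir, "panel.json")) as fh:
            meta = json.load(fh)
        from .reference import ReferencePanel
        b = bulk
        if not np.array_equal(bulk.gene_ids, cells.gene_ids):
            b, cells = align_genes(bulk, cells)
        panel = ReferencePanel(cells=cells, variant=variant,
                               held_out=meta["held_out"])
        res = deconvolve(b, panel, backend=config.backend)
        res.save(os.path.join(d, f"proportions_{variant}.csv"))
        results[variant] = res
    _write_manifest(d, "deconvolve", config, [],
                    {"backend": config.backend})
    return results


def _stage_evaluate(config: RunConfig):
    d_pb = _stage_dir(config, "pseudobulk")
    props_path = _require(os.path.join(d_pb, "proportions.csv"),
                          "pseudobulk", "evaluate")
    truth = pd.read_csv(props_path, index_col=0)
    d_dec = _stage_dir(config, "deconvolve")
    d = _stage_dir(config, "evaluate", create=True)
    records = []
    for variant in config.transforms:
        path = _require(os.path.join(d_dec, f"proportions_{variant}.csv"),
                        "deconvolve", "evaluate")
        est = pd.read_csv(path, index_col=0)
        with open(os.path.join(_stage_dir(config, "transform"), variant,
                               "panel.json")) as fh:
            held = json.load(fh)["held_out"]
        types = [c for c in truth.columns if c in est.columns]
        t_mat = truth[types].values
        e_mat = est[types].values
        held_idx = types.index(held) if held in types else None
        for i, sid in enumerate(truth.index):
            p, r = score_sample(t_mat[i], e_mat[i], "all")
            records.append(EvaluationRecord(config.dataset_name, variant,
                                            held, "all", sid, p, r))
            if held_idx is not None:
                p, r = score_sample(t_mat[i], e_mat[i], "non_removed",
                                    held_out_index=held_idx)
                records.append(EvaluationRecord(config.dataset_name, variant,
                                                held, "non_removed", sid,
                                                p, r))
        if held_idx is not None:
            p, r = score_removed(t_mat[:, held_idx], e_mat[:, held_idx])
            records.append(EvaluationRecord(config.dataset_name, variant,
                                            held, "removed_only", "pooled",
                                            p, r))
    df = records_to_frame(records)
    df.to_csv(os.path.join(d, "evaluation.csv"), index=False)
    _write_manifest(d, "evaluate", config, [props_path], {})
    return records


def _stage_report(config: RunConfig):
    d_ev = _stage_dir(config, "evaluate")
    path = _require(os.path.join(d_ev, "evaluation.csv"), "evaluate", "report")
    df = pd.read_csv(path)
    d = _stage_dir(config, "report", create=True)
    rows = []
    seed = derive_seed(config.master_seed, "report", "ci")
    for (variant, scen), sub in df.groupby(["transform", "scenario"]):
        vals = sub["pearson"].dropna().values
        if len(vals) == 0:
            continue
        mean, lo, hi = bootstrap_mean_ci(vals, seed=seed)
        rmean, rlo, rhi = bootstrap_mean_ci(sub["rmse"].dropna().values,
                                            seed=seed)
        rows.append({"transform": variant, "scenario": scen,
                     "pearson_mean": mean, "pearson_lo": lo,
                     "pearson_hi": hi, "rmse_mean": rmean,
                     "rmse_lo": rlo, "rmse_hi": rhi, "n": len(sub)})
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(d, "summary.csv"), index=False)
    try:
        scores = composite_scores(df)
        scores.to_frame().to_csv(os.path.join(d, "composite_scores.csv"))
    except ValueError as exc:
        logger.warning("composite scores skipped: %s", exc)
        scores = None
    _write_manifest(d, "report", config, [path], {})
    return summary, scores
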