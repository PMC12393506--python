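# modref

Modality-aware integration of single-nucleus RNA-seq into single-cell
deconvolution references.

## The problem

Bulk RNA-seq deconvolution estimates the cell-type proportions **p** of
a bulk sample **b** from a reference of cell-type expression profiles:
with a signature matrix **S** (types × genes, one CPM-scale profile per
type), the built-in solver computes

    ŵ = argmin_{w ≥ 0} ‖Sᵀw − b‖₂ ,   p̂ = ŵ / Σ ŵ .

References are usually built from scRNA-seq, but dissociation-sensitive
cell types (adipocytes, neurons, neutrophils, …) are often only
captured by single-nucleus RNA-seq — which measures nuclear, not
cytoplasmic, transcripts. Appending snRNA-seq profiles to an scRNA-seq
reference "as is" therefore injects a systematic modality bias into
exactly the cell types the reference was missing.

`modref` is a benchmarking framework for the strategies that bridge
this gap, for computational biologists evaluating or building
deconvolution pipelines:

* **DEG pruning** — remove genes differentially expressed between
  modalities (per cell type, per dataset, or intersected across
  datasets) from the reference gene space. DE is tested on 10-cell
  aggregates with a negative-binomial Wald test and Benjamini-Hochberg
  adjustment at padj < 0.01.
* **PCA neighbour shift** — move each nucleus cell's coordinates in a
  75%-variance PCA space by the mean modality-correction vector of its
  10 nearest nucleus neighbours of overlapping types.
* **VAE latent shift / conditional VAE label switch** — an scVI-style
  negative-binomial variational autoencoder (2 hidden layers, 30 latent
  dimensions, gene-by-modality dispersion); either the same neighbour
  shift applied in latent space, or encoding a nucleus cell with its
  true modality label and decoding with the cell label.

Everything runs under a *held-out protocol*: one cell type at a time is
removed from the scRNA reference and re-supplied from snRNA-seq, and
every model is trained without that type — mimicking the real situation
where the missing type has no scRNA-seq examples at all. A synthetic
paired-modality generator (shared expression programs, known
modality-effect genes, donors, library-size variation) makes the whole
loop testable without downloads, and pseudobulks of known composition
provide exact ground truth.

## Worked example

```python
import numpy as np

from modref.benchmark import run_benchmark
from modref.evaluate import bootstrap_mean_ci

res = run_benchmark(seed=7, variants=("pos_ctrl", "neg_ctrl",
                                      "sn_raw", "sn_deg"))
print("held-out type:", res.held_out)
for v in ("pos_ctrl", "neg_ctrl", "sn_raw", "sn_deg"):
    vals = res.pearson_values(v)
    mean, lo, hi = bootstrap_mean_ci(vals[~np.isnan(vals)], seed=0)
    print(f"{v:10s} mean Pearson {mean:.3f}  (95% CI {lo:.3f}-{hi:.3f})")
```

```
held-out type: typeA
pos_ctrl   mean Pearson 0.994  (95% CI 0.993-0.996)
neg_ctrl   mean Pearson 0.866  (95% CI 0.830-0.894)
sn_raw     mean Pearson 0.859  (95% CI 0.834-0.884)
sn_deg     mean Pearson 0.984  (95% CI 0.980-0.988)
```

One seed of the benchmark: 100 pseudobulks built from one synthetic
scRNA sample are deconvolved against four references assembled from an
independent sample of the same tissue. The all-scRNA positive control
(`pos_ctrl`, 0.994) and the all-snRNA negative control (`neg_ctrl`,
0.866) bracket the problem; appending the held-out type's nucleus cells
raw (`sn_raw`, 0.859) is no better than the negative control, while
pruning the 206 cross-modality DEGs first (`sn_deg`, 0.984) recovers
nearly all of the positive control's accuracy — the framework's central
observation.

The same loop is scriptable stage by stage from a shell:

```
modref run --config config.yaml --seed 1 --output-dir myrun
modref report --config config.yaml --output-dir myrun
```

Each stage writes its artifacts plus a manifest (parameters, seeds,
input hashes); reruns with the same seed are bit-identical.

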