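"""Negative-binomial variational autoencoder for modality transformation.

Architecture follows the scVI configuration found to work well in
alignment tasks: encoder and decoder with two hidden layers, a
30-dimensional latent space, a negative-binomial observation likelihood
and a gene-by-modality ("gene-batch") dispersion parameter. In the
conditional variant the modality label is one-hot encoded at the encoder
input and injected again at the latent space, so a nucleus cell can be
encoded with its true label and decoded with the cell label to impute a
whole-cell-like profile.

The network is implemented directly in numpy (forward pass, analytic
gradients, Adam), trained by minibatch SGD on the NB evidence lower
bound with a 90/10 train/validation split and early stopping with
patience 10. All randomness flows through one seeded generator, so a
fixed seed reproduces the training trajectory exactly.

Two transformations hang off a trained model:

* latent-space shift (non-conditional model): nucleus cells of the
  missing type are encoded, shifted by the mean stored shift of their
  k nearest overlapping-nucleus neighbours (exactly as in the PCA
  transform, but in the VAE latent space) and decoded;
* conditional label switch: missing cells are encoded with the nucleus
  one-hot and decoded with the cell one-hot.

Decoded mean expression is rescaled so every cell totals L, the median
library size of the scRNA training cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .containers import LabeledCounts
from .pca_shift import knn_mean_shift, rescale_rows

logger = logging.getLogger(__name__)

MODALITY_INDEX = {"cell": 0, "nucleus": 1}


# ----------------------------------------------------------------------
# parameter initialisation and Adam

def _glorot(rng, n_in, n_out):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(o):
    o = o - o.max(axis=1, keepdims=True)
    e = np.exp(o)
    return e / e.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------

@dataclass
class VAEConfig:
    n_hidden: int = 128
    n_latent: int = 30
    learning_rate: float = 1e-3
    # small minibatches keep the number of gradient steps useful on
    # reference-sized training pools (hundreds of cells, short schedules)
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    kl_weight: float = 1.0


@dataclass
class VAEModel:
    """Trained NB-VAE with its parameters and training metadata."""

    gene_ids: np.ndarray
    conditional: bool
    config: VAEConfig
    params: dict
    n_batches: int = 2
    seed: int = 0
    train_history: list = field(default_factory=list)
    val_history: list = field(default_factory=list)

    # -- forward pieces ---------------------------------------------
    def _encoder_input(self, x, onehot):
        xin = np.log1p(x)
        if self.conditional:
            xin = np.hstack([xin, onehot])
        return xin

    def encode(self, x, modality_idx=None):
        """Posterior means (and log-variances) of the latent coordinates."""
        onehot = self._onehot(modality_idx, x.shape[0])
        p = self.params
        h1 = _relu(self._encoder_input(x, onehot) @ p["We1"] + p["be1"])
        h2 = _relu(h1 @ p["We2"] + p["be2"])
        mu = h2 @ p["Wmu"] + p["bmu"]
        logvar = np.clip(h2 @ p["Wlv"] + p["blv"], -10.0, 10.0)
        return mu, logvar

    def decode(self, z, modality_idx=None):
        """Per-gene mean fractions rho (rows sum to 1)."""
        onehot = self._onehot(modality_idx, z.shape[0])
        p = self.params
        zin = np.hstack([z, onehot]) if self.conditional else z
        h1 = _relu(zin @ p["Wd1"] + p["bd1"])
        h2 = _relu(h1 @ p["Wd2"] + p["bd2"])
        return _softmax(h2 @ p["Wout"] + p["bout"])

    def _onehot(self, modality_idx, n):
        if not self.conditional:
            return None
        if modality_idx is None:
            raise ValueError("conditional model requires a modality label")
        idx = np.broadcast_to(np.asarray(modality_idx, dtype=int), (n,))
        oh = np.zeros((n, self.n_batches))
        oh[np.arange(n), idx] = 1.0
        return oh

    def reconstruct(self, x, modality_idx=None, target_library=None):
        """Encode at the posterior mean and decode with the same label."""
        mu, _ = self.encode(x, modality_idx)
        rho = self.decode(mu, modality_idx)
        lib = (x.sum(axis=1, keepdims=True) if target_library is None
               else target_library)
        return rho * lib


def nb_log_likelihood(y, mean, theta):
    """Elementwise NB log-pmf with mean/dispersion parameterization."""
    mean = np.maximum(mean, 1e-10)
    theta = np.maximum(theta, 1e-10)
    return (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
            + theta * (np.log(theta) - np.log(theta + mean))
            + y * (np.log(mean) - np.log(theta + mean)))


def _init_params(rng, n_genes, n_hidden, n_latent, conditional, n_batches):
    n_in = n_genes + (n_batches if conditional else 0)
    n_zin = n_latent + (n_batches if conditional else 0)
    return {
        "We1": _glorot(rng, n_in, n_hidden), "be1": np.zeros(n_hidden),
        "We2": _glorot(rng, n_hidden, n_hidden), "be2": np.zeros(n_hidden),
        "Wmu": _glorot(rng, n_hidden, n_latent), "bmu": np.zeros(n_latent),
        "Wlv": _glorot(rng, n_hidden, n_latent), "blv": np.zeros(n_latent),
        "Wd1": _glorot(rng, n_zin, n_hidden), "bd1": np.zeros(n_hidden),
        "Wd2": _glorot(rng, n_hidden, n_hidden), "bd2": np.zeros(n_hidden),
        "Wout": _glorot(rng, n_hidden, n_genes), "bout": np.zeros(n_genes),
        "log_theta": np.zeros((n_batches, n_genes)),
    }


def _forward_backward(params, x, batch_idx, conditional, n_batches, rng,
                      kl_weight):
    """One minibatch ELBO evaluation with analytic gradients.

    Returns (mean loss per cell, grads dict). x is raw counts.
    """
    n, n_genes = x.shape
    lib = x.sum(axis=1, keepdims=True)
    oh = None
    if conditional:
        oh = np.zeros((n, n_batches))
        oh[np.arange(n), batch_idx] = 1.0

    xin = np.log1p(x)
    if conditional:
        xin = np.hstack([xin, oh])

    # encoder forward
    a1 = xin @ params["We1"] + params["be1"]; h1 = _relu(a1)
    a2 = h1 @ params["We2"] + params["be2"]; h2 = _relu(a2)
    mu = h2 @ params["Wmu"] + params["bmu"]
    logvar = np.clip(h2 @ params["Wlv"] + params["blv"], -10.0, 10.0)
    sigma = np.exp(0.5 * logvar)
    eps = rng.standard_normal(mu.shape)
    z = mu + sigma * eps

    # decoder forward
    zin = np.hstack([z, oh]) if conditional else z
    b1 = zin @ params["Wd1"] + params["bd1"]; g1 = _relu(b1)
    b2 = g1 @ params["Wd2"] + params["bd2"]; g2 = _relu(b2)
    o = g2 @ params["Wout"] + params["bout"]
    rho = _softmax(o)
    m = np.maximum(rho * lib, 1e-10)
    theta = np.exp(params["log_theta"])[batch_idx]  # (n, n_genes)

    nll = -nb_log_likelihood(x, m, theta)
    kl = 0.5 * (mu ** 2 + np.exp(logvar) - logvar - 1.0)
    loss = (nll.sum(axis=1) + kl_weight * kl.sum(axis=1)).mean()

    grads = {}
    inv_n = 1.0 / n
    # --- NB likelihood gradients
    dL_dm = ((theta + x) / (theta + m) - x / m) * inv_n
    # softmax jacobian: d m/d o through rho, scaled by lib
    a = dL_dm * lib
    do = rho * (a - (a * rho).sum(axis=1, keepdims=True))
    # dispersion gradient (per batch row)
    dnll_dtheta = -(digamma(x + theta) - digamma(theta)
                    + np.log(theta) - np.log(theta + m)
                    + 1.0 - (theta + x) / (theta + m))
    dlt = dnll_dtheta * theta * inv_n
    g_log_theta = np.zeros_like(params["log_theta"])
    np.add.at(g_log_theta, batch_idx, dlt)
    grads["log_theta"] = g_log_theta

    # --- decoder backprop
    grads["Wout"] = g2.T @ do; grads["bout"] = do.sum(axis=0)
    dg2 = do @ params["Wout"].T
    db2 = dg2 * (b2 > 0)
    grads["Wd2"] = g1.T @ db2; grads["bd2"] = db2.sum(axis=0)
    dg1 = db2 @ params["Wd2"].T
    db1 = dg1 * (b1 > 0)
    grads["Wd1"] = zin.T @ db1; grads["bd1"] = db1.sum(axis=0)
    dzin = db1 @ params["Wd1"].T
    dz = dzin[:, : mu.shape[1]]

    # --- KL + reparameterization
    dmu = dz + kl_weight * mu * inv_n
    dlogvar = dz * sigma * eps * 0.5 \
        + kl_weight * 0.5 * (np.exp(logvar) - 1.0) * inv_n
    dlogvar = dlogvar * ((logvar > -10.0) & (logvar < 10.0))

    # --- encoder backprop
    grads["Wmu"] = h2.T @ dmu; grads["bmu"] = dmu.sum(axis=0)
    grads["Wlv"] = h2.T @ dlogvar; grads["blv"] = dlogvar.sum(axis=0)
    dh2 = dmu @ params["Wmu"].T + dlogvar @ params["Wlv"].T
    da2 = dh2 * (a2 > 0)
    grads["We2"] = h1.T @ da2; grads["be2"] = da2.sum(axis=0)
    dh1 = da2 @ params["We2"].T
    da1 = dh1 * (a1 > 0)
    grads["We1"] = xin.T @ da1; grads["be1"] = da1.sum(axis=0)
    return loss, grads


def elbo_loss(model: VAEModel, x, batch_idx, rng=None):
    """Monte-Carlo ELBO loss (mean per cell) at the posterior mean."""
    mu, logvar = model.encode(x, batch_idx if model.conditional else None)
    rho = model.decode(mu, batch_idx if model.conditional else None)
    lib = x.sum(axis=1, keepdims=True)
    m = np.maximum(rho * lib, 1e-10)
    theta = np.exp(model.params["log_theta"])[np.asarray(batch_idx, dtype=int)]
    nll = -nb_log_likelihood(x, m, theta).sum(axis=1)
    kl = 0.5 * (mu ** 2 + np.exp(logvar) - logvar - 1.0).sum(axis=1)
    return float((nll + kl).mean())


def save_vae(model: VAEModel, path: str) -> None:
    """Serialize weights as .npz plus a JSON manifest."""
    import json
    import os
    from dataclasses import asdict
    os.makedirs(path, exist_ok=True)
    np.savez(os.path.join(path, "weights.npz"),
             gene_ids=model.gene_ids.astype(str), **model.params)
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump({"conditional": model.conditional,
                   "config": asdict(model.config),
                   "seed": model.seed,
                   "n_batches": model.n_batches,
                   "train_history": model.train_history,
                   "val_history": model.val_history}, fh, indent=1)


def load_vae(path: str) -> VAEModel:
    import json
    import os
    with open(os.path.join(path, "manifest.json")) as fh:
        meta = json.load(fh)
    with np.load(os.path.join(path, "weights.npz"),
                 allow_pickle=False) as z:
        gene_ids = z["gene_ids"].astype(object)
        params = {k: z[k] for k in z.files if k != "gene_ids"}
    return VAEModel(gene_ids=gene_ids, conditional=meta["conditional"],
                    config=VAEConfig(**meta["config"]), params=params,
                    n_batches=meta["n_batches"], seed=meta["seed"],
                    train_history=meta["train_history"],
                    val_history=meta["val_history"])


def fit_vae(train: LabeledCounts, conditional: bool = False,
            config: VAEConfig | None = None, seed: int = 0,
            held_out=None) -> VAEModel:
    """Train the NB-VAE on integer counts by minibatch Adam.

    ``held_out``, when given, is asserted absent from the training data —
    the held-out protocol requires that the model never sees the type it
    will later impute.
    """
    if held_out is not None and held_out in set(train.cell_type):
        raise ValueError(f"held-out type {held_out!r} present in training data")
    x = train.dense().astype(float)
    if not np.allclose(x, np.round(x)):
        raise ValueError("VAE training requires integer counts")
    batch_idx = np.array([MODALITY_INDEX[m] for m in train.modality])
    if conditional and len(set(batch_idx.tolist())) < 2:
        raise ValueError("conditional model needs both modalities in training")
    cfg = config or VAEConfig()
    rng = np.random.default_rng(seed)
    params = _init_params(rng, x.shape[1], cfg.n_hidden, cfg.n_latent,
                          conditional, 2)
    opt = _Adam(params, lr=cfg.learning_rate)
    n = x.shape[0]
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    model = VAEModel(gene_ids=train.gene_ids.copy(), conditional=conditional,
                     config=cfg, params=params, seed=seed)
    best_val = np.inf
    best_params = None
    stall = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(tr_idx)
        ep_losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            loss, grads = _forward_backward(
                params, x[sel], batch_idx[sel], conditional, 2, rng,
                cfg.kl_weight)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"VAE training diverged at epoch {epoch}")
            opt.step(params, grads)
            ep_losses.append(loss)
        val = elbo_loss(model, x[val_idx], batch_idx[val_idx])
        model.train_history.append(float(np.mean(ep_losses)))
        model.val_history.append(val)
        if val < best_val - 1e-6:
            best_val = val
            best_params = {k: v.copy() for k, v in params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                logger.info("early stop at epoch %d (best val %.3f)",
                            epoch, best_val)
                break
    if best_params is not None:
        model.params = best_params
    return model


def _median_library(sc_train: LabeledCounts) -> float:
    return float(np.median(sc_train.library_sizes()))


def apply_latent_shift(model: VAEModel, sn_overlap: LabeledCounts,
                       sn_missing: LabeledCounts, sc_train: LabeledCounts,
                       k: int = 10) -> LabeledCounts:
    """k-NN mean-shift of missing nucleus cells in the VAE latent space."""
    if model.conditional:
        raise ValueError("latent shift uses the non-conditional model")
    for lc in (sn_overlap, sn_missing, sc_train):
        if not np.array_equal(lc.gene_ids, model.gene_ids):
            raise ValueError("inputs must be gene-aligned to the model")
    z_sc, _ = model.encode(sc_train.dense().astype(float))
    z_ov, _ = model.encode(sn_overlap.dense().astype(float))
    z_mi, _ = model.encode(sn_missing.dense().astype(float))
    # per-type scRNA centroids, as in the PCA shift: each overlapping
    # nucleus cell stores the vector to its own type's scRNA centroid
    shifts = np.empty_like(z_ov)
    for t in np.unique(sn_overlap.cell_type):
        sc_mask = sc_train.cell_type == t
        sn_mask = sn_overlap.cell_type == t
        if not sc_mask.any():
            raise ValueError(f"overlap type {t!r} has no scRNA training cells")
        shifts[sn_mask] = z_sc[sc_mask].mean(axis=0)[None, :] - z_ov[sn_mask]
    shift = knn_mean_shift(z_mi, z_ov, shifts, k)
    rho = model.decode(z_mi + shift)
    L = _median_library(sc_train)
    out = rescale_rows(np.clip(rho, 0.0, None), L)
    return LabeledCounts(
        values=out, gene_ids=sn_missing.gene_ids.copy(),
        cell_type=sn_missing.cell_type.copy(),
        modality=sn_missing.modality.copy(),
        donor=sn_missing.donor.copy(),
        dataset_tag=sn_missing.dataset_tag + "_scvi_ls",
    )


def apply_conditional(model: VAEModel, sn_missing: LabeledCounts,
                      target_library: float) -> LabeledCounts:
    """Encode missing cells with the nucleus label, decode with the cell
    label, and rescale every decoded profile to the target library size."""
    if not model.conditional:
        raise ValueError("label switching requires a conditional model")
    if not np.array_equal(sn_missing.gene_ids, model.gene_ids):
        raise ValueError("input must be gene-aligned to the model")
    x = sn_missing.dense().astype(float)
    mu, _ = model.encode(x, MODALITY_INDEX["nucleus"])
    rho = model.decode(mu, MODALITY_INDEX["cell"])
    out = rescale_rows(np.clip(rho, 0.0, None), target_library)
    return LabeledCounts(
        values=out, gene_ids=sn_missing.gene_ids.copy(),
        cell_type=sn_missing.cell_type.copy(),
        modality=sn_missing.modality.copy(),
        donor=sn_missing.donor.copy(),
        dataset_tag=sn_missing.dataset_tag + "_scvi_cond",
    )
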