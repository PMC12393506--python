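"""Accuracy, similarity, robustness and composite scoring.

Per-sample deconvolution accuracy is Pearson correlation and RMSE
between true and estimated proportion vectors, under three scenarios:
``all`` (every type), ``non_removed`` (held-out type dropped from both
vectors) and ``removed_only`` (the held-out type's proportion pooled
across samples — per-sample correlation on a scalar is undefined, so
this scenario yields one record per dataset × transform × held-out
type).

Robustness on real bulks without ground truth is measured as cosine
similarity of predicted proportion matrices, flattened to long vectors:
between transforms (same donors) and between donors (same transform).

The composite scores min-max scale each metric family to [0, 1] within
its population and average: accuracy = mean of normalized Pearson and
normalized inverted RMSE (scaled within dataset, averaged per transform,
then across datasets); robustness = mean of the per-donor and
per-transform components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LabeledCounts

logger = logging.getLogger(__name__)

SCENARIOS = ("all", "non_removed", "removed_only")

#: two-sample test significance level for control comparisons;
#: deliberately conservative, and configurable per analysis
DEFAULT_SIGNIFICANCE = 0.005


@dataclass
class EvaluationRecord:
    dataset: str
    transform: str
    held_out: object
    scenario: str
    sample_id: str
    pearson: float
    rmse: float

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ----------------------------------------------------------------------
# elementary metrics

def _pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        logger.warning("constant vector: Pearson undefined, returning NaN")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _rmse(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def score_sample(true_p, est_p, scenario: str = "all", held_out_index=None):
    """Pearson and RMSE of one sample's proportion vectors.

    ``non_removed`` drops the held-out entry from both vectors first.
    """
    true_p = np.asarray(true_p, dtype=float)
    est_p = np.asarray(est_p, dtype=float)
    if true_p.shape != est_p.shape:
        raise ValueError("proportion vectors must be aligned")
    if scenario == "non_removed":
        if held_out_index is None:
            raise ValueError("non_removed scenario needs the held-out index")
        keep = np.arange(len(true_p)) != held_out_index
        true_p, est_p = true_p[keep], est_p[keep]
    elif scenario == "removed_only":
        raise ValueError("use score_removed for the removed_only scenario")
    return _pearson(true_p, est_p), _rmse(true_p, est_p)


def score_removed(true_col, est_col):
    """Pooled metrics for the held-out type's proportion across samples."""
    return _pearson(true_col, est_col), _rmse(true_col, est_col)


def bootstrap_mean_ci(values, n_boot: int = 1000, level: float = 0.95,
                      seed: int = 0):
    """Percentile bootstrap CI of the mean; deterministic under seed."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite values to bootstrap")
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, len(v)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(v.mean()), float(lo), float(hi)


def t_test_equal_var(a, b):
    """Two-tailed pooled-variance t-test; missing values dropped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two finite values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero pooled variance
        equal = np.isclose(a.mean(), b.mean())
        return (0.0, 1.0) if equal else (np.inf, 0.0)
    return float(t), float(p)


def _cosine(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine of a zero vector is undefined")
    return float(np.dot(u, v) / (nu * nv))


def cosine_profiles(a: LabeledCounts, b: LabeledCounts, cell_type,
                    n_cells: int = 50, seed: int = 0) -> float:
    """Cosine similarity of 50-cell aggregate CPM/log1p type profiles.

    Each side samples ``n_cells`` cells of the type (with replacement if
    fewer are available), sums them, CPM-scales and log1p-transforms, so
    the similarity reflects relative expression patterns rather than
    sequencing depth.
    """
    vecs = []
    for lc in (a, b):
        # one generator per side: identical inputs under the same seed
        # sample identical cells, so cosine(a, a) is exactly 1
        rng = np.random.default_rng(seed)
        pool = np.flatnonzero(lc.cell_type == cell_type)
        if len(pool) == 0:
            raise ValueError(f"type {cell_type!r} absent")
        replace = len(pool) < n_cells
        if replace:
            logger.info("type %s: %d cells available, sampling %d with "
                        "replacement", cell_type, len(pool), n_cells)
        chosen = rng.choice(pool, size=n_cells, replace=replace)
        profile = lc.dense().astype(float)[chosen].sum(axis=0)
        total = profile.sum()
        if total <= 0:
            raise ValueError("zero aggregate profile")
        vecs.append(np.log1p(profile * (1e6 / total)))
    return _cosine(vecs[0], vecs[1])


def cosine_proportions(res_a, res_b) -> float:
    """Cosine of two proportion matrices flattened row-major."""
    pa, pb = res_a.proportions, res_b.proportions
    if pa.shape != pb.shape:
        raise ValueError("results must share samples and types")
    if res_a.cell_types != res_b.cell_types:
        raise ValueError("results must share the cell-type order")
    return _cosine(pa.ravel(), pb.ravel())


# ----------------------------------------------------------------------
# robustness and composite scores

@dataclass
class RobustnessTable:
    """Inter-transform and inter-donor cosine similarities."""

    transforms: list
    transform_matrix: np.ndarray          # symmetric, diagonal = 1
    donor_matrices: dict                  # transform -> (n_donor, n_donor)

    def off_diagonal(self, transform: str) -> np.ndarray:
        i = self.transforms.index(transform)
        row = np.concatenate([self.transform_matrix[i, :i],
                              self.transform_matrix[i, i + 1:]])
        return row

    def donor_pairs(self, transform: str) -> np.ndarray:
        m = self.donor_matrices[transform]
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]

    def save(self, path: str) -> None:
        """Write the cosine matrices as square CSVs under ``path``."""
        import os
        os.makedirs(path, exist_ok=True)
        pd.DataFrame(self.transform_matrix, index=self.transforms,
                     columns=self.transforms).to_csv(
            os.path.join(path, "transform_cosine.csv"))
        for t, m in self.donor_matrices.items():
            pd.DataFrame(m).to_csv(
                os.path.join(path, f"donor_cosine_{t}.csv"))


def robustness_from_results(per_transform: dict,
                            per_donor: dict = None) -> RobustnessTable:
    """Build the robustness table from DeconvolutionResults.

    ``per_transform`` maps transform -> result on the same bulks;
    ``per_donor`` maps transform -> {donor -> result}.
    """
    transforms = sorted(per_transform)
    n = len(transforms)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c = cosine_proportions(per_transform[transforms[i]],
                                   per_transform[transforms[j]])
            mat[i, j] = mat[j, i] = c
    donor_mats = {}
    if per_donor:
        for tname, donors in per_donor.items():
            keys = sorted(donors)
            dm = np.eye(len(keys))
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    c = cosine_proportions(donors[keys[i]], donors[keys[j]])
                    dm[i, j] = dm[j, i] = c
            donor_mats[tname] = dm
    return RobustnessTable(transforms=transforms, transform_matrix=mat,
                           donor_matrices=donor_mats)


def minmax(values: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant population maps to 0 (logged)."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        logger.warning("degenerate min-max population; scores set to 0")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


@dataclass
class CompositeScores:
    accuracy_score: dict                  # transform -> [0,1]
    robustness_score: dict                # transform -> [0,1]
    accuracy_components: pd.DataFrame = None
    robustness_components: pd.DataFrame = None

    def to_frame(self) -> pd.DataFrame:
        transforms = sorted(set(self.accuracy_score)
                            | set(self.robustness_score))
        return pd.DataFrame({
            "transform": transforms,
            "accuracy_score": [self.accuracy_score.get(t, np.nan)
                               for t in transforms],
            "robustness_score": [self.robustness_score.get(t, np.nan)
                                 for t in transforms],
        }).set_index("transform")


def composite_scores(records, robustness: RobustnessTable = None
                     ) -> CompositeScores:
    """Accuracy and robustness composites per transform.

    Accuracy: within each dataset, min-max the per-sample Pearson values
    and the inverted RMSE values across all records; average each per
    transform; average across datasets; the score is the mean of the two
    normalized metrics. Robustness: min-max the pooled donor-pair
    cosines and the pooled off-diagonal transform-pair cosines, average
    each per transform, and take the mean of the two components.
    """
    df = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    if df["transform"].nunique() < 2:
        raise ValueError("composite scoring needs at least two transforms")
    acc_rows = []
    for ds, sub in df.groupby("dataset"):
        sub = sub.dropna(subset=["pearson", "rmse"])
        norm_p = minmax(sub["pearson"].values)
        inv_rmse = sub["rmse"].max() - sub["rmse"].values
        norm_r = minmax(inv_rmse)
        tmp = pd.DataFrame({"transform": sub["transform"].values,
                            "norm_pearson": norm_p, "norm_rmse": norm_r})
        per_t = tmp.groupby("transform").mean()
        per_t["dataset"] = ds
        acc_rows.append(per_t.reset_index())
    acc = pd.concat(acc_rows, ignore_index=True)
    collapsed = acc.groupby("transform")[["norm_pearson", "norm_rmse"]].mean()
    accuracy = ((collapsed["norm_pearson"] + collapsed["norm_rmse"]) / 2.0
                ).to_dict()

    robustness_score = {}
    rob_components = None
    if robustness is not None:
        transforms = robustness.transforms
        pooled_t = np.concatenate([robustness.off_diagonal(t)
                                   for t in transforms])
        scaled_t = minmax(pooled_t)
        per_transform_score = {}
        cursor = 0
        for t in transforms:
            n = len(robustness.off_diagonal(t))
            per_transform_score[t] = float(scaled_t[cursor:cursor + n].mean())
            cursor += n
        per_donor_score = {}
        if robustness.donor_matrices:
            pooled_d = np.concatenate([robustness.donor_pairs(t)
                                       for t in transforms
                                       if t in robustness.donor_matrices])
            scaled_d = minmax(pooled_d)
            cursor = 0
            for t in transforms:
                if t not in robustness.donor_matrices:
                    continue
                n = len(robustness.donor_pairs(t))
                per_donor_score[t] = float(scaled_d[cursor:cursor + n].mean())
                cursor += n
        for t in transforms:
            parts = [per_transform_score[t]]
            if t in per_donor_score:
                parts.append(per_donor_score[t])
            robustness_score[t] = float(np.mean(parts))
        rob_components = pd.DataFrame({
            "transform": transforms,
            "per_transform": [per_transform_score[t] for t in transforms],
            "per_donor": [per_donor_score.get(t, np.nan) for t in transforms],
        }).set_index("transform")

    return CompositeScores(accuracy_score=accuracy,
                           robustness_score=robustness_score,
                           accuracy_components=collapsed,
                           robustness_components=rob_components)
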