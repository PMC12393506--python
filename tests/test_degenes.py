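import logging

import numpy as np
import pytest

from modref.containers import BulkMatrix, LabeledCounts
from modref.degenes import (benjamini_hochberg, build_catalog, de_test,
                            make_aggregates, nb_wald_engine, prune_genes)


def stratified_counts(n_per_stratum, n_genes=30, seed=0, mean=5.0):
    """Cells over (type, modality) strata with NB-ish counts."""
    rng = np.random.default_rng(seed)
    rows, types, mods = [], [], []
    for (ctype, mod), n in n_per_stratum.items():
        rows.append(rng.poisson(mean, size=(n, n_genes)))
        types.extend([ctype] * n)
        mods.extend([mod] * n)
    values = np.vstack(rows)
    return LabeledCounts(
        values=values,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cell_type=np.array(types, dtype=object),
        modality=np.array(mods, dtype=object),
        donor=np.array(["d"] * len(types), dtype=object),
    )


class TestMakeAggregates:
    def test_floor_division_discards_remainder(self):
        lc = stratified_counts({("A", "cell"): 25})
        agg = make_aggregates(lc, group_size=10, seed=0)
        assert agg.values.shape[0] == 2
        used = np.concatenate(agg.membership)
        assert len(used) == 20 and len(set(used.tolist())) == 20

    def test_aggregate_equals_sum_of_members(self):
        lc = stratified_counts({("A", "cell"): 23, ("A", "nucleus"): 31})
        agg = make_aggregates(lc, group_size=10, seed=1)
        dense = lc.dense()
        for i, members in enumerate(agg.membership):
            np.testing.assert_array_equal(agg.values[i],
                                          dense[members].sum(axis=0))

    def test_group_size_one_is_permutation_of_cells(self):
        lc = stratified_counts({("A", "cell"): 7})
        agg = make_aggregates(lc, group_size=1, seed=2)
        assert sorted(map(tuple, agg.values)) == \
            sorted(map(tuple, lc.dense()))

    def test_low_replicate_strata_flagged(self):
        lc = stratified_counts({("A", "cell"): 25, ("B", "cell"): 60})
        agg = make_aggregates(lc, group_size=10, seed=3)
        flagged = {t for t, m, n in agg.low_replicate_strata}
        assert flagged == {"A"}

    def test_non_integer_input_rejected(self):
        lc = stratified_counts({("A", "cell"): 10})
        lc.values = lc.values + 0.5
        with pytest.raises(ValueError, match="integer"):
            make_aggregates(lc)


class TestBenjaminiHochberg:
    def test_three_value_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_direct_stepup_formula(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        adj = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running_min = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running_min = min(running_min, p[i] * m / rank_from_top)
            expected[i] = running_min
        np.testing.assert_allclose(adj, expected)
        assert np.all(adj >= p - 1e-15)

    def test_nan_propagates(self):
        adj = benjamini_hochberg([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and np.isfinite(adj[0])


def nb_counts(rng, mean, theta, size):
    lam = rng.gamma(theta, mean / theta, size=size)
    return rng.poisson(lam)


class TestDeTest:
    def test_null_calibration(self):
        """Both groups from the same NB: the fraction of padj<0.01 calls
        stays at or below twice the nominal rate."""
        fracs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            means = rng.lognormal(2.0, 1.0, size=500)
            counts = nb_counts(rng, means[None, :], 5.0, (40, 500))
            is_nuc = np.arange(40) >= 20
            _, p = nb_wald_engine(counts, is_nuc)
            padj = benjamini_hochberg(p)
            fracs.append(np.mean(padj[np.isfinite(padj)] < 0.01))
        assert np.mean(fracs) <= 0.02

    def test_fourfold_gene_detected(self):
        rng = np.random.default_rng(9)
        means = np.full(200, 20.0)
        counts = nb_counts(rng, means[None, :], 10.0, (40, 200))
        counts[20:, 0] = nb_counts(rng, 80.0, 10.0, 20)  # 4x in nucleus
        is_nuc = np.arange(40) >= 20
        lfc, p = nb_wald_engine(counts, is_nuc)
        padj = benjamini_hochberg(p)
        assert padj[0] < 0.01
        assert 1.0 < lfc[0] < 3.0  # log2 scale, truth = 2

    def test_all_zero_genes_returned_missing(self):
        lc = stratified_counts({("A", "cell"): 40, ("A", "nucleus"): 40})
        lc.values[:, 5] = 0
        agg = make_aggregates(lc, group_size=10, seed=0)
        res = de_test(agg, "A")
        assert np.isnan(res.pvalue[5]) and np.isnan(res.padj[5])

    def test_missing_modality_raises(self):
        lc = stratified_counts({("A", "cell"): 40})
        agg = make_aggregates(lc, group_size=10, seed=0)
        with pytest.raises(ValueError, match="nucleus"):
            de_test(agg, "A")

    def test_padj_at_least_p(self):
        lc = stratified_counts({("A", "cell"): 50, ("A", "nucleus"): 50})
        agg = make_aggregates(lc, group_size=10, seed=1)
        res = de_test(agg, "A")
        ok = np.isfinite(res.pvalue)
        assert np.all(res.padj[ok] >= res.pvalue[ok] - 1e-15)

    def test_pluggable_engine(self):
        lc = stratified_counts({("A", "cell"): 20, ("A", "nucleus"): 20})
        agg = make_aggregates(lc, group_size=10, seed=0)

        def fake_engine(counts, is_nucleus):
            n = counts.shape[1]
            return np.zeros(n), np.full(n, 0.5)

        res = de_test(agg, "A", engine=fake_engine)
        assert np.all(res.pvalue == 0.5)


def test_default_engine_agrees_with_pydeseq2(caplog):
    """Cross-check against the DESeq2-compatible reference implementation
    on a fixed synthetic input. Engines differ in dispersion shrinkage,
    so the agreement (Jaccard of DEG sets) is logged, not enforced."""
    pytest.importorskip("pydeseq2")
    import pandas as pd
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(21)
    n_genes = 400
    means = rng.lognormal(2.5, 1.0, size=n_genes)
    counts = nb_counts(rng, means[None, :], 8.0, (30, n_genes))
    is_nuc = np.arange(30) >= 15
    shifted = rng.choice(n_genes, 40, replace=False)
    counts[15:, shifted] = nb_counts(
        rng, means[shifted][None, :] * 3.0, 8.0, (15, len(shifted)))

    lfc, p = nb_wald_engine(counts, is_nuc)
    ours = set(np.flatnonzero(benjamini_hochberg(p) < 0.01).tolist())

    meta = pd.DataFrame({"condition": np.where(is_nuc, "nucleus", "cell")})
    dds = DeseqDataSet(counts=pd.DataFrame(counts), metadata=meta,
                       design="~condition", quiet=True)
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "nucleus", "cell"],
                       quiet=True)
    stats.summary()
    theirs = set(np.flatnonzero(stats.results_df["padj"] < 0.01).tolist())

    union = ours | theirs
    jaccard = len(ours & theirs) / len(union) if union else 1.0
    logging.getLogger(__name__).info(
        "DEG cross-check Jaccard vs pydeseq2: %.3f (ours %d, theirs %d)",
        jaccard, len(ours), len(theirs))
    assert 0.0 <= jaccard <= 1.0


def de_result_from_sets(gene_ids, sig):
    from modref.degenes import DEResult
    p = np.where(np.isin(gene_ids, list(sig)), 1e-6, 0.5)
    return DEResult(gene_ids=np.asarray(gene_ids, dtype=object),
                    log2_fold_change=np.zeros(len(gene_ids)),
                    pvalue=p, padj=p)


class TestBuildCatalog:
    universe = np.array([f"g{i}" for i in range(10)], dtype=object)

    def test_intersection_matches_set_algebra(self):
        de = {
            ("dsA", "t1"): de_result_from_sets(self.universe, {"g1", "g2"}),
            ("dsA", "t2"): de_result_from_sets(self.universe, {"g2", "g3"}),
            ("dsB", "t1"): de_result_from_sets(self.universe, {"g2", "g4"}),
        }
        cat = build_catalog(de, ["dsA", "dsB"], self.universe)
        assert cat.per_dataset_union["dsA"] == {"g1", "g2", "g3"}
        assert cat.intersection_across_datasets == {"g2"}
        assert cat.other_datasets_union["dsA"] == {"g2", "g4"}
        assert cat.other_datasets_union["dsB"] == {"g1", "g2", "g3"}

    def test_held_out_only_de_type_gives_empty_union(self):
        de = {("dsA", "t1"): de_result_from_sets(self.universe, {"g1"})}
        cat = build_catalog(de, ["dsA"], self.universe, held_out="t1")
        assert cat.per_dataset_union["dsA"] == set()

    def test_random_matched_size(self):
        de = {("dsA", "t1"): de_result_from_sets(self.universe,
                                                 {"g1", "g5", "g7"})}
        for seed in (0, 1, 2):
            cat = build_catalog(de, ["dsA"], self.universe, random_seed=seed)
            assert len(cat.random_matched["dsA"]) == 3
            assert cat.random_matched["dsA"] <= set(self.universe.tolist())

    def test_intersection_subset_of_every_union(self):
        rng = np.random.default_rng(6)
        de = {}
        for ds in ("d1", "d2", "d3"):
            for t in ("a", "b"):
                sig = set(rng.choice(self.universe, 4, replace=False))
                de[(ds, t)] = de_result_from_sets(self.universe, sig)
        cat = build_catalog(de, ["d1", "d2", "d3"], self.universe)
        for ds in ("d1", "d2", "d3"):
            assert cat.intersection_across_datasets <= \
                cat.per_dataset_union[ds]
            others = set().union(*(cat.per_dataset_union[d]
                                   for d in ("d1", "d2", "d3") if d != ds))
            assert cat.other_datasets_union[ds] == others

    def test_unknown_dataset_rejected(self):
        de = {("dsX", "t"): de_result_from_sets(self.universe, {"g1"})}
        with pytest.raises(ValueError, match="unknown dataset"):
            build_catalog(de, ["dsA"], self.universe)


class TestPruneGenes:
    def lc(self):
        return LabeledCounts(
            values=np.arange(12).reshape(3, 4),
            gene_ids=np.array(["a", "b", "c", "d"], dtype=object),
            cell_type=np.array(["A"] * 3, dtype=object),
            modality=np.array(["cell"] * 3, dtype=object),
            donor=np.array(["d"] * 3, dtype=object),
        )

    def test_empty_removal_is_identity(self):
        lc = self.lc()
        out = prune_genes(lc, set())
        np.testing.assert_array_equal(out.dense(), lc.dense())
        assert list(out.gene_ids) == list(lc.gene_ids)

    def test_keep_single_gene(self):
        out = prune_genes(self.lc(), {"a", "b", "d"})
        assert list(out.gene_ids) == ["c"]
        np.testing.assert_array_equal(out.dense().ravel(), [2, 6, 10])

    def test_remove_everything_rejected(self):
        with pytest.raises(ValueError, match="empty gene set"):
            prune_genes(self.lc(), {"a", "b", "c", "d"})

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_set_difference_on_bulk(self, seed):
        rng = np.random.default_rng(seed)
        genes = np.array([f"g{i}" for i in range(20)], dtype=object)
        bulk = BulkMatrix(values=rng.random((3, 20)), gene_ids=genes,
                          sample_ids=np.array(["s1", "s2", "s3"],
                                              dtype=object))
        remove = set(rng.choice(genes, 7, replace=False).tolist())
        out = prune_genes(bulk, remove)
        expected = [g for g in genes if g not in remove]
        assert list(out.gene_ids) == expected
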