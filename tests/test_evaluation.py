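"""Enrichment, EHR permutation validation, and consistency indices."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from amend.evaluation import (
    GeneSetCollection,
    bootstrap_index_pvalue,
    ehr,
    hypergeom_ora,
    jaccard,
    module_stats,
    nested,
)
from amend.network import InteractionNetwork, Module


@pytest.fixture
def universe20():
    genes = [f"g{i:02d}" for i in range(20)]
    return genes, GeneSetCollection.from_dict({"S": genes[:5]}, genes)


class TestModuleStats:
    def test_path_summary(self, path3):
        stats = pd.DataFrame(
            {"eci": [-0.5, -0.7, -0.9], "z": [0.0, 1.0, 2.0]},
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        mod = Module.from_nodes(path3, ["a", "b", "c"])
        out = module_stats(mod, stats)
        assert out["median_eci"] == pytest.approx(-0.7)
        assert out["edge_density"] == pytest.approx(2 / 3)
        assert out["proportion_significant"] is None

    def test_single_node_density_zero(self, path3):
        stats = pd.DataFrame({"eci": [0.1]}, index=pd.Index(["a"], name="gene_id"))
        out = module_stats(Module.from_nodes(path3, ["a"]), stats)
        assert out["edge_density"] == 0.0

    def test_all_flags_true(self, path3):
        stats = pd.DataFrame(
            {"eci": [0.1, 0.2, 0.3], "significant": [True, True, True]},
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        out = module_stats(Module.from_nodes(path3, ["a", "b", "c"]), stats)
        assert out["proportion_significant"] == 1.0


class TestHypergeomORA:
    def test_worked_example(self, universe20):
        genes, coll = universe20
        module = genes[2:6]  # overlap 3 with the 5-gene set
        out = hypergeom_ora(module, coll)
        assert out.loc["S", "overlap"] == 3
        assert out.loc["S", "pvalue"] == pytest.approx(155 / 4845, rel=1e-12)

    def test_zero_overlap_p_is_one(self, universe20):
        genes, coll = universe20
        out = hypergeom_ora(genes[10:13], coll)
        assert out.loc["S", "pvalue"] == pytest.approx(1.0)

    def test_module_equals_universe_p_one(self, universe20):
        genes, _ = universe20
        coll = GeneSetCollection.from_dict({"S": genes}, genes)
        out = hypergeom_ora(genes, coll)
        assert out.loc["S", "pvalue"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        # p-value from the closed-form tail equals brute-force enumeration
        # over all equally likely modules of the same size
        genes = [f"g{i}" for i in range(10)]
        gene_set = genes[:4]
        coll = GeneSetCollection.from_dict({"S": gene_set}, genes)
        for module_size in (2, 3, 5):
            for module in combinations(genes, module_size):
                x = len(set(module) & set(gene_set))
                count = sum(
                    1
                    for cand in combinations(genes, module_size)
                    if len(set(cand) & set(gene_set)) >= x
                )
                expected = count / comb(10, module_size)
                p = hypergeom_ora(module, coll).loc["S", "pvalue"]
                assert p == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(60)]
        sets = {
            f"S{j}": list(rng.choice(genes, size=8, replace=False)) for j in range(12)
        }
        coll = GeneSetCollection.from_dict(sets, genes)
        out = hypergeom_ora(genes[:10], coll)
        assert (out["adjusted_pvalue"] >= out["pvalue"] - 1e-15).all()
        ranks_raw = out["pvalue"].rank(method="average")
        ranks_adj = out["adjusted_pvalue"].rank(method="average")
        # adjusted ordering never inverts the raw ordering
        assert ((ranks_raw - ranks_adj).abs() < 1e-9).all() or (
            out.sort_values("pvalue")["adjusted_pvalue"].is_monotonic_increasing
        )


class TestEHR:
    def _setup(self):
        genes = [f"g{i:02d}" for i in range(30)]
        coll = GeneSetCollection.from_dict(
            {"hit": genes[:6], "miss": genes[20:26]}, genes
        )
        module = genes[:6]
        return genes, coll, [module]

    def test_null_replicating_original_gives_zero(self):
        genes, coll, modules = self._setup()
        out = ehr(modules, lambda b: modules, coll, n_permutations=5)
        assert out["ehr"] == 0.0

    def test_empty_null_gives_one(self):
        genes, coll, modules = self._setup()
        # permuted runs find nothing: scores all 0, empirical p = 0
        out = ehr(modules, lambda b: [genes[10:13]], coll, n_permutations=5)
        assert out["ehr"] == 1.0

    def test_empirical_p_on_permutation_grid(self):
        genes, coll, modules = self._setup()
        out = ehr(modules, lambda b: [genes[b : b + 4]], coll, n_permutations=8)
        grid = np.arange(9) / 8
        for p in out["empirical_pvalues"]:
            assert np.isclose(grid, p).any()

    def test_no_significant_sets_reports_unavailable(self):
        genes = [f"g{i:02d}" for i in range(30)]
        coll = GeneSetCollection.from_dict({"S": genes[20:26]}, genes)
        out = ehr([genes[:4]], lambda b: [genes[:4]], coll, n_permutations=3)
        assert out["ehr"] is None

    def test_manual_empirical_p(self):
        # null scores (0,1,2,3) against an observed score of 2 -> p = 0.5
        null = np.array([0.0, 1.0, 2.0, 3.0])
        p = (null >= 2.0).mean()
        assert p == 0.5


class TestConsistencyIndices:
    def test_identical_sets(self):
        assert jaccard("abc", "abc") == 1.0
        assert nested("abc", "abc") == 1.0

    def test_disjoint_sets(self):
        assert jaccard(["a"], ["b"]) == 0.0
        assert nested(["a"], ["b"]) == 0.0

    def test_worked_values(self):
        a = {"g1", "g2", "g3", "g4"}
        b = {"g3", "g4", "g5", "g6", "g7", "g8"}
        assert jaccard(a, b) == pytest.approx(0.25)
        assert nested(a, b) == pytest.approx(0.5)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            jaccard([], ["a"])

    def test_nested_dominates_jaccard_random_pairs(self):
        rng = np.random.default_rng(1)
        genes = np.array([f"g{i:03d}" for i in range(40)])
        for _ in range(1000):
            a = rng.choice(genes, size=rng.integers(1, 20), replace=False)
            b = rng.choice(genes, size=rng.integers(1, 20), replace=False)
            j, n = jaccard(a, b), nested(a, b)
            assert 0.0 <= j <= n <= 1.0


class TestBootstrap:
    def test_disjoint_modules_p_one(self):
        uni = [f"g{i:02d}" for i in range(30)]
        out = bootstrap_index_pvalue(uni[:5], uni[5:10], uni, n_boot=200, seed=0)
        assert out["jaccard_pvalue"] == 1.0
        assert out["nested_pvalue"] == 1.0

    def test_deterministic_under_seed(self):
        uni = [f"g{i:02d}" for i in range(40)]
        a, b = uni[:12], uni[6:20]
        r1 = bootstrap_index_pvalue(a, b, uni, n_boot=1000, seed=42)
        r2 = bootstrap_index_pvalue(a, b, uni, n_boot=1000, seed=42)
        assert r1 == r2

    def test_strong_overlap_low_p(self):
        uni = [f"g{i:02d}" for i in range(60)]
        a = uni[:10]
        b = uni[:9] + [uni[20]]
        out = bootstrap_index_pvalue(a, b, uni, n_boot=500, seed=3)
        assert out["jaccard_pvalue"] <= 0.05
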