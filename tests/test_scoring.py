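"""Gene scoring, aggregation, coexpression and distance-decay diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcea import (
    ExpressionAtlas,
    PhenotypeMap,
    aggregate_category_scores,
    category_cge,
    compute_distance_matrix,
    fit_exp_decay,
    region_class_differential,
    score_genes,
    within_category_coexpression,
)
from gcea.ontology import Category, CategoryTable
from gcea.scoring import GeneScoreTable


def _atlas_from(values: dict, index=None) -> ExpressionAtlas:
    return ExpressionAtlas(pd.DataFrame(values, index=index))


def _phen(values, index) -> PhenotypeMap:
    return PhenotypeMap(pd.Series(values, index=index))


class TestScoreGenes:
    idx = [f"r{i}" for i in range(5)]

    def test_self_and_negated_correlation(self):
        y = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        atlas = _atlas_from({"same": y, "neg": -y}, self.idx)
        out = score_genes(atlas, _phen(y, self.idx))
        assert out.scores["same"] == pytest.approx(1.0)
        assert out.scores["neg"] == pytest.approx(-1.0)

    def test_spearman_ties_use_average_ranks(self):
        # hand computation: x = (1, 2, 2, 4, 5) -> average ranks (1, 2.5, 2.5, 4, 5),
        # y = (10, 20, 30, 40, 50) -> ranks (1..5); rank deviations from mean 3:
        # dx = (-2, -0.5, -0.5, 1, 2), dy = (-2, -1, 0, 1, 2)
        # sum dx dy = 9.5, sum dx^2 = 9.5, sum dy^2 = 10
        # rho = 9.5 / sqrt(9.5 * 10) = 0.9746794...
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        atlas = _atlas_from({"g": x}, self.idx)
        out = score_genes(atlas, _phen(y, self.idx), method="spearman")
        assert out.scores["g"] == pytest.approx(9.5 / np.sqrt(9.5 * 10.0))

    def test_pearson_invariant_to_affine_phenotype_rescaling(self):
        rng = np.random.default_rng(0)
        idx = [f"r{i}" for i in range(20)]
        atlas = _atlas_from({f"g{j}": rng.standard_normal(20) for j in range(5)}, idx)
        y = rng.standard_normal(20)
        a = score_genes(atlas, _phen(y, idx)).scores
        b = score_genes(atlas, _phen(3.5 * y - 2.0, idx)).scores
        pd.testing.assert_series_equal(a, b)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        idx = [f"r{i}" for i in range(20)]
        atlas = _atlas_from({f"g{j}": rng.standard_normal(20) for j in range(5)}, idx)
        y = rng.standard_normal(20)
        a = score_genes(atlas, _phen(y, idx), method="spearman").scores
        b = score_genes(atlas, _phen(np.exp(y), idx), method="spearman").scores
        pd.testing.assert_series_equal(a, b)

    def test_constant_phenotype_is_error(self):
        atlas = _atlas_from({"g": np.arange(5.0)}, self.idx)
        with pytest.raises(ValueError, match="constant"):
            score_genes(atlas, _phen(np.ones(5), self.idx))

    def test_constant_gene_dropped(self):
        atlas = _atlas_from({"flat": np.ones(5), "ok": np.arange(5.0)}, self.idx)
        out = score_genes(atlas, _phen(np.arange(5.0), self.idx))
        assert "flat" not in out.gene_ids
        assert "ok" in out.gene_ids

    def test_pairwise_complete_missing_handling(self):
        x = np.array([np.nan, 1.0, 2.0, 3.0, 4.0])
        y = np.array([9.0, 1.0, 2.0, 3.0, 4.0])
        atlas = _atlas_from({"g": x}, self.idx)
        out = score_genes(atlas, _phen(y, self.idx))
        assert out.scores["g"] == pytest.approx(1.0)
        assert out.table.loc["g", "n_used"] == 4


class TestAggregation:
    def _scores(self, vals: dict) -> GeneScoreTable:
        df = pd.DataFrame({"score": pd.Series(vals), "n_used": 10})
        return GeneScoreTable(df, method="pearson")

    def test_raw_and_absolute_means(self):
        scores = self._scores({"a": 0.4, "b": -0.4})
        cats = CategoryTable([Category("C1", "c", frozenset({"a", "b"}))])
        assert aggregate_category_scores(scores, cats, "raw")["score"]["C1"] == pytest.approx(0.0)
        assert aggregate_category_scores(scores, cats, "absolute")["score"]["C1"] == pytest.approx(0.4)

    def test_singleton_category_identity(self):
        scores = self._scores({"a": 0.123})
        cats = CategoryTable([Category("C1", "c", frozenset({"a"}))])
        assert aggregate_category_scores(scores, cats)["score"]["C1"] == pytest.approx(0.123)

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(2)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(-1, 1, 10))}
        scores = self._scores(vals)
        cats = CategoryTable([Category("C1", "c", frozenset(vals))])
        brute = sum(vals.values()) / len(vals)
        assert aggregate_category_scores(scores, cats)["score"]["C1"] == pytest.approx(brute)

    def test_unscored_members_shrink_size(self):
        scores = self._scores({"a": 0.5, "b": 0.1})
        cats = CategoryTable([Category("C1", "c", frozenset({"a", "b", "zz"}))])
        out = aggregate_category_scores(scores, cats)
        assert out.loc["C1", "size"] == 2
        cats_empty = CategoryTable([Category("C2", "c", frozenset({"zz"}))])
        assert aggregate_category_scores(scores, cats_empty).empty


class TestCoexpression:
    def test_identical_genes_give_one(self):
        v = np.arange(6.0)
        atlas = _atlas_from({"a": v, "b": v}, [f"r{i}" for i in range(6)])
        assert within_category_coexpression(atlas, {"a", "b"}) == pytest.approx(1.0)

    def test_invariant_to_gene_order(self, small_atlas):
        atlas, cats = small_atlas
        genes = list(cats.categories[0].genes)
        a = within_category_coexpression(atlas, genes)
        b = within_category_coexpression(atlas, genes[::-1])
        assert a == pytest.approx(b)

    def test_three_gene_manual_mean(self):
        rng = np.random.default_rng(5)
        idx = [f"r{i}" for i in range(8)]
        cols = {g: rng.standard_normal(8) for g in "abc"}
        atlas = _atlas_from(cols, idx)
        manual = np.mean([
            stats.spearmanr(cols["a"], cols["b"]).statistic,
            stats.spearmanr(cols["a"], cols["c"]).statistic,
            stats.spearmanr(cols["b"], cols["c"]).statistic,
        ])
        assert within_category_coexpression(atlas, "abc") == pytest.approx(manual)

    def test_iid_noise_category_near_zero(self):
        rng = np.random.default_rng(6)
        idx = [f"r{i}" for i in range(50)]
        genes = {f"g{j}": rng.standard_normal(50) for j in range(30)}
        atlas = _atlas_from(genes, idx)
        r = within_category_coexpression(atlas, genes)
        # pairwise null correlations have sd ~ 1/sqrt(n-1); the mean of 435
        # positively dependent pairs stays well inside 3 x that single-pair sd
        assert abs(r) < 3.0 / np.sqrt(49)

    def test_requires_two_genes(self, small_atlas):
        atlas, _ = small_atlas
        with pytest.raises(ValueError, match="2 genes"):
            within_category_coexpression(atlas, {"g00001"})


class TestCategoryCGE:
    def _spatial_atlas(self, n=6, g=5, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"r{i}" for i in range(n)]
        expr = pd.DataFrame(rng.standard_normal((n, g)), index=idx,
                            columns=[f"g{j}" for j in range(g)])
        coords = pd.DataFrame(rng.uniform(0, 10, (n, 3)), index=idx, columns=list("xyz"))
        return ExpressionAtlas(expr, coordinates=coords)

    def test_identical_region_profiles_give_cge_one(self):
        atlas = self._spatial_atlas()
        atlas.expression.iloc[1] = atlas.expression.iloc[0]
        d = compute_distance_matrix(atlas)
        pairs = category_cge(atlas, atlas.gene_ids, d)
        row = pairs[(pairs.region_i == "r0") & (pairs.region_j == "r1")]
        assert row["cge"].iloc[0] == pytest.approx(1.0)

    def test_pair_count(self):
        atlas = self._spatial_atlas(n=7)
        pairs = category_cge(atlas, atlas.gene_ids, compute_distance_matrix(atlas))
        assert len(pairs) == 7 * 6 // 2

    def test_matches_bruteforce_per_pair_pearson(self):
        atlas = self._spatial_atlas(n=4, g=5, seed=3)
        d = compute_distance_matrix(atlas)
        pairs = category_cge(atlas, atlas.gene_ids, d)
        x = atlas.expression.to_numpy()
        for _, row in pairs.iterrows():
            i = list(atlas.region_ids).index(row.region_i)
            j = list(atlas.region_ids).index(row.region_j)
            assert row.cge == pytest.approx(np.corrcoef(x[i], x[j])[0, 1])

    def test_requires_three_genes(self):
        atlas = self._spatial_atlas()
        with pytest.raises(ValueError, match="3 genes"):
            category_cge(atlas, ["g0", "g1"], compute_distance_matrix(atlas))


class TestExpDecayFit:
    def test_exact_model_recovered(self):
        d = np.arange(0.0, 11.0)
        y = 1.0 * np.exp(-d / 2.0)
        fit = fit_exp_decay(d, y)
        assert fit.A == pytest.approx(1.0, abs=1e-6)
        assert fit.lam == pytest.approx(2.0, abs=1e-6)
        assert fit.B == pytest.approx(0.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_has_low_r2(self):
        rng = np.random.default_rng(8)
        d = np.linspace(0, 10, 200)
        fit = fit_exp_decay(d, rng.standard_normal(200))
        assert fit.r2 < 0.1
        assert abs(fit.alt_spearman_stat) < 0.3

    def test_matches_grid_search_oracle_on_noisy_decay(self):
        rng = np.random.default_rng(9)
        d = np.linspace(0, 12, 120)
        y = 0.8 * np.exp(-d / 3.0) + 0.1 + rng.normal(0, 0.02, 120)
        fit = fit_exp_decay(d, y)
        # dense grid over (A, lam, B)
        As = np.linspace(0.5, 1.1, 41)
        ls = np.linspace(1.0, 6.0, 101)
        Bs = np.linspace(-0.1, 0.3, 41)
        best, best_sse = None, np.inf
        for lam in ls:
            e = np.exp(-d / lam)
            for A in As:
                pred0 = A * e
                for B in Bs:
                    sse = ((y - pred0 - B) ** 2).sum()
                    if sse < best_sse:
                        best_sse, best = sse, (A, lam, B)
        assert fit.A == pytest.approx(best[0], abs=0.05)
        assert fit.lam == pytest.approx(best[1], abs=0.2)
        assert fit.B == pytest.approx(best[2], abs=0.05)

    def test_spearman_alternative_is_positive_for_decay(self):
        d = np.arange(0.0, 20.0)
        fit = fit_exp_decay(d, np.exp(-d / 5.0))
        assert fit.alt_spearman_stat == pytest.approx(1.0)

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_exp_decay([1.0, 1.0, 2.0, 3.0], [1.0, 1.0, 0.5, 0.2])


class TestRegionClassDifferential:
    def _atlas(self, a_vals, b_vals, n_extra=0, seed=0):
        rng = np.random.default_rng(seed)
        na, nb = len(a_vals), len(b_vals)
        idx = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
        data = {"g0": np.concatenate([a_vals, b_vals])}
        for j in range(n_extra):
            data[f"x{j}"] = rng.standard_normal(na + nb)
        labels = pd.Series(["A"] * na + ["B"] * nb, index=idx)
        return ExpressionAtlas(pd.DataFrame(data, index=idx), region_class=labels)

    def test_perfect_separation_exact_p(self):
        # all five A values exceed all five B values: exact two-sided
        # rank-sum p = 2 * (1 / C(10,5)) = 2 / 252
        atlas = self._atlas(np.arange(10.0, 15.0), np.arange(0.0, 5.0))
        out = region_class_differential(atlas)
        assert out.loc["g0", "p"] == pytest.approx(2.0 / 252.0)

    def test_identical_distributions_large_p(self):
        vals = np.arange(10.0)
        atlas = self._atlas(vals, vals)
        out = region_class_differential(atlas)
        assert out.loc["g0", "p"] > 0.9

    def test_single_gene_q_equals_p(self):
        atlas = self._atlas(np.arange(10.0, 15.0), np.arange(0.0, 5.0))
        out = region_class_differential(atlas)
        assert out.loc["g0", "q"] == pytest.approx(out.loc["g0", "p"])
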