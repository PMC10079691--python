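"""Robust regression, transforms, clustering, attribution and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsnet.datamodel import ExpressionMatrix
from prsnet.interpret import (
    cell_type_specific_genes,
    endophenotype_assoc,
    enrichment_test,
    group_mean_comparison,
    kmeans_cluster,
    multivariate_module_assoc,
    rank_inverse_normal,
    robust_linear_fit,
    spearman_partial_correlation,
)

from conftest import make_pheno


class TestRankInverseNormal:
    def test_blom_closed_form_n3(self):
        z = rank_inverse_normal([10.0, 2.0, 5.0])
        # ranks (3,1,2); (r - 3/8)/(3 + 1 - 3/4)
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(z, expected, atol=1e-12)
        assert z[1] == pytest.approx(-0.8694, abs=2e-4)

    def test_symmetry_and_ties(self, rng):
        z = rank_inverse_normal(rng.normal(size=101))
        assert abs(z.mean()) < 1e-10
        z2 = rank_inverse_normal([1.0, 2.0, 2.0, 5.0])
        assert z2[1] == z2[2]

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(rank_inverse_normal(x),
                                   rank_inverse_normal(np.exp(3 * x)),
                                   atol=1e-12)

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            rank_inverse_normal([1.0, 1.0, 1.0])


class TestRobustFit:
    def test_clean_data_matches_ols(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.0 + 2.0 * X[:, 1] + rng.normal(0, 0.05, n)
        fit = robust_linear_fit(y, X)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, ols, atol=1e-3)
        assert fit.weights.max() <= 1.0 + 1e-9

    def test_outlier_resistance(self):
        wins = 0
        reps = 200
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            n = 100
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(0, 0.3, n)
            y[0] += 30.0  # one gross outlier
            X = np.column_stack([np.ones(n), x])
            truth = np.array([0.0, 0.5])
            robust = robust_linear_fit(y, X).params
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            if np.linalg.norm(robust - truth) < np.linalg.norm(ols - truth):
                wins += 1
        assert wins >= 0.95 * reps

    def test_rank_deficiency_named(self):
        X = np.column_stack([np.ones(10), np.zeros(10)])
        with pytest.raises(ValueError, match="rank deficient"):
            robust_linear_fit(np.arange(10.0), X, names=["intercept", "zero"])


class TestEndophenotypeAssoc:
    def test_power_by_construction(self):
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(700 + seed)
            n = 2000
            predictor = rng.normal(size=n)
            biomarker = 0.3 * predictor + rng.normal(0, 1.0, n)
            pheno = make_pheno(
                np.where(rng.random(n) < 0.5, "AD", "NC"),
                biomarker=biomarker,
            )
            fit = endophenotype_assoc(predictor, "biomarker", pheno)
            if fit.pvalues[1] < 0.05:
                detected += 1
        assert detected == 5

    def test_null_p_uniform(self):
        pvals = []
        for r in range(200):
            rng = np.random.default_rng(900 + r)
            n = 120
            predictor = rng.normal(size=n)
            pheno = make_pheno(
                np.where(rng.random(n) < 0.5, "AD", "NC"),
                biomarker=rng.normal(size=n),
            )
            fit = endophenotype_assoc(predictor, "biomarker", pheno,
                                      covariates=[])
            pvals.append(fit.pvalues[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_predictor_error(self):
        pheno = make_pheno(["AD", "NC"] * 10, biomarker=np.zeros(20))
        with pytest.raises(ValueError, match="constant"):
            endophenotype_assoc(np.ones(20), "biomarker", pheno)


class TestMultivariateModules:
    def test_correct_module_gets_max_t(self, rng):
        n = 1000
        modules = rng.normal(size=(n, 5))
        endo = modules[:, 1] + rng.normal(0, 0.5, n)
        pheno = make_pheno(np.where(rng.random(n) < 0.5, "AD", "NC"))
        t = multivariate_module_assoc(modules, endo, pheno)
        assert t.abs().idxmax() == "module2"

    def test_null_t_small(self):
        big = 0
        for r in range(30):
            rng = np.random.default_rng(40 + r)
            n = 1000
            modules = rng.normal(size=(n, 5))
            endo = rng.normal(size=n)
            pheno = make_pheno(np.where(rng.random(n) < 0.5, "AD", "NC"))
            t = multivariate_module_assoc(modules, endo, pheno, covariates=[])
            if t.abs().max() >= 3:
                big += 1
        assert big <= 3  # max|t| < 3 in >= 90% of replicates

    def test_collinear_modules_error(self, rng):
        m = rng.normal(size=(100, 2))
        modules = np.column_stack([m, m[:, 0]])
        pheno = make_pheno(["AD", "NC"] * 50)
        with pytest.raises(ValueError, match="collinear"):
            multivariate_module_assoc(modules, rng.normal(size=100), pheno)


class TestKmeans:
    def test_two_blobs_elbow(self, rng):
        X = np.vstack([rng.normal(0, 0.3, size=(40, 2)),
                       rng.normal(5, 0.3, size=(40, 2))])
        res = kmeans_cluster(X, range(1, 7), seed=0)
        assert res.chosen_k == 2
        ks = sorted(res.wss)
        wss = [res.wss[k] for k in ks]
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))

    def test_identical_points_choose_one(self):
        X = np.ones((10, 3))
        res = kmeans_cluster(X, [1, 2, 3], seed=0)
        assert res.chosen_k == 1
        assert set(res.assignments) == {1}

    def test_determinism_and_stability(self, rng):
        X = np.vstack([rng.normal(0, 0.2, size=(30, 2)),
                       rng.normal(4, 0.2, size=(30, 2)),
                       rng.normal([0, 8], 0.2, size=(30, 2))])
        first = kmeans_cluster(X, range(1, 7), seed=5)
        again = kmeans_cluster(X, range(1, 7), seed=5)
        np.testing.assert_array_equal(first.assignments, again.assignments)
        chosen = {kmeans_cluster(X, range(1, 7), seed=s).chosen_k
                  for s in range(10)}
        assert chosen == {3}

    def test_k_exceeds_rows(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(np.zeros((3, 2)), [1, 5], seed=0)


def brute_force_partial_spearman(score, D, j):
    """Residualize rank(score) and rank(D_j) on the other ranked variants."""
    ranks = np.apply_along_axis(stats.rankdata, 0,
                                np.column_stack([score, D]))
    target_a = ranks[:, 0]
    target_b = ranks[:, j + 1]
    controls = np.delete(ranks[:, 1:], j, axis=1)
    Z = np.column_stack([np.ones(len(score)), controls])
    ra = target_a - Z @ np.linalg.lstsq(Z, target_a, rcond=None)[0]
    rb = target_b - Z @ np.linalg.lstsq(Z, target_b, rcond=None)[0]
    return np.corrcoef(ra, rb)[0, 1]


class TestPartialSpearman:
    def test_two_variables_reduces_to_spearman(self, rng):
        score = rng.normal(size=100)
        d = 0.5 * score + rng.normal(size=100)
        res = spearman_partial_correlation(score, d)
        plain = stats.spearmanr(score, d).statistic
        assert res.table.loc[0, "rho"] == pytest.approx(plain, abs=1e-10)

    def test_exact_sum_relation(self, rng):
        g1 = rng.integers(0, 3, 4000).astype(float)
        g2 = rng.integers(0, 3, 4000).astype(float)
        score = g1 + g2
        res = spearman_partial_correlation(score, np.column_stack([g1, g2]))
        assert res.table["rho"].min() > 0.9

    def test_null_variant_near_zero(self, rng):
        n = 5000
        g = rng.integers(0, 3, size=(n, 3)).astype(float)
        score = g[:, 0] + rng.normal(0, 0.5, n)
        res = spearman_partial_correlation(score, g)
        assert abs(res.table.loc[1, "rho"]) < 0.05
        assert abs(res.table.loc[2, "rho"]) < 0.05

    def test_matches_residualize_oracle(self, rng):
        n, m = 150, 5
        D = rng.normal(size=(n, m))
        score = D @ rng.normal(size=m) + rng.normal(size=n)
        res = spearman_partial_correlation(score, D)
        for j in range(m):
            oracle = brute_force_partial_spearman(score, D, j)
            assert res.table.loc[j, "rho"] == pytest.approx(oracle, abs=1e-6)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        n = 120
        D = rng.normal(size=(n, 3))
        score = D[:, 0] + rng.normal(size=n)
        res = spearman_partial_correlation(score, D)
        df = pd.DataFrame(np.column_stack([score, D]),
                          columns=["s", "a", "b", "c"])
        ref = pg.partial_corr(df, x="a", y="s", covar=["b", "c"],
                              method="spearman")
        assert res.table.loc[0, "rho"] == pytest.approx(
            float(ref["r"].iloc[0]), abs=1e-10)

    def test_duplicate_variant_singular(self, rng):
        d = rng.normal(size=50)
        with pytest.raises(ValueError, match="singular|duplicate"):
            spearman_partial_correlation(rng.normal(size=50),
                                         np.column_stack([d, d]))


class TestCellTypeSpecific:
    def expr(self, rows):
        return ExpressionMatrix(pd.DataFrame(
            rows, index=[f"G{i}" for i in range(len(rows))],
            columns=["B", "T", "NK"],
        ))

    def test_threshold_rules(self):
        labels = cell_type_specific_genes(self.expr([
            [10.0, 1.0, 1.0],   # specific to B: expressed and 10x others
            [4.0, 1.0, 1.0],    # below expressed threshold 5
            [10.0, 8.0, 1.0],   # ratio 1.25 < 1.5 -> unlabeled
            [9.0, 6.0, 1.0],    # 1.5x exactly -> labeled
        ]))
        assert labels == {"G0": "B", "G3": "B"}

    def test_needs_two_cell_types(self):
        e = ExpressionMatrix(pd.DataFrame([[10.0]], index=["G"], columns=["B"]))
        with pytest.raises(ValueError, match="two cell types"):
            cell_type_specific_genes(e)


def exact_hypergeom_tail(overlap, n_bg, set_size, cluster_size):
    total = 0.0
    for k in range(overlap, min(set_size, cluster_size) + 1):
        total += (math.comb(set_size, k)
                  * math.comb(n_bg - set_size, cluster_size - k)
                  / math.comb(n_bg, cluster_size))
    return total


class TestEnrichment:
    def test_matches_exact_enumeration(self):
        background = [f"g{i}" for i in range(60)]
        sets = {"B": background[:10], "T": background[10:25]}
        cluster = background[:5] + background[30:35]
        res = enrichment_test(cluster, sets, background)
        for _, row in res.table.iterrows():
            expected = exact_hypergeom_tail(
                int(row["overlap"]), 60, int(row["set_size"]), 10)
            assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_cluster_equals_set_minimal_p(self):
        background = [f"g{i}" for i in range(100)]
        sets = {"B": background[:10], "T": background[10:20]}
        res = enrichment_test(background[:10], sets, background)
        t = res.table.set_index("cell_type")
        assert t.loc["B", "p"] < t.loc["T", "p"]
        assert t.loc["B", "overlap"] == 10

    def test_null_p_roughly_uniform(self):
        background = [f"g{i}" for i in range(200)]
        sets = {"B": background[:40]}
        pvals = []
        for r in range(150):
            rng = np.random.default_rng(60 + r)
            cluster = list(rng.choice(background, size=20, replace=False))
            pvals.append(enrichment_test(cluster, sets, background)
                         .table["p"].iloc[0])
        # discrete p-values: check mean is near 0.5-ish, not degenerate
        assert 0.35 < np.mean(pvals) < 0.75

    def test_cluster_outside_background_error(self):
        with pytest.raises(ValueError, match="subset"):
            enrichment_test(["x"], {"B": ["g1"]}, ["g1", "g2"])


class TestGroupComparison:
    def test_two_groups_f_equals_t_squared(self, rng):
        values = rng.normal(size=40)
        groups = np.repeat(["a", "b"], 20)
        res = group_mean_comparison(values, groups)
        t = res["pairwise"].loc[0, "t"]
        assert res["f"] == pytest.approx(t**2, rel=1e-9)

    def test_null_f_p_uniform(self):
        pvals = []
        for r in range(200):
            rng = np.random.default_rng(80 + r)
            values = rng.normal(size=60)
            groups = np.repeat(["a", "b", "c"], 20)
            pvals.append(group_mean_comparison(values, groups)["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_bonferroni_never_below_raw(self, rng):
        values = rng.normal(size=60)
        groups = np.repeat(["a", "b", "c"], 20)
        pw = group_mean_comparison(values, groups)["pairwise"]
        assert (pw["p_bonferroni"] >= pw["p_raw"] - 1e-12).all()
        assert (pw["p_bonferroni"] <= 1.0).all()

    def test_singleton_group_excluded(self, rng):
        values = rng.normal(size=41)
        groups = np.array(["a"] * 20 + ["b"] * 20 + ["c"])
        with pytest.warns(UserWarning, match="fewer than two"):
            res = group_mean_comparison(values, groups)
        assert set(res["pairwise"]["group_a"]) | set(res["pairwise"]["group_b"]) \
            == {"a", "b"}
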