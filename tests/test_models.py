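"""Polygenic-score model families: weighted PRS, lasso, neural nets, graphs."""

import numpy as np
import pytest

from prsnet.assoc import logistic_irls
from prsnet.metrics import auroc
from prsnet.models import (
    NeuralPRSModel,
    TrainConfig,
    WeightedPRSModel,
    build_nn,
    fit_lasso,
    lr_at_step,
    nn_score,
    penultimate_outputs,
    train_nn,
    weighted_prs,
)
from prsnet.models.gnn import build_graphs, train_gnn, gnn_score
from prsnet.models.lasso import _cd_logistic_path

from conftest import make_geno, make_pheno


class TestWeightedPRS:
    def test_arithmetic(self):
        g = make_geno([[0, 1, 2.0]])
        model = WeightedPRSModel(["rs1", "rs2", "rs3"], [0.5, -0.2, 1.0])
        assert model.score(g)[0] == pytest.approx(1.8)
        assert model.score(make_geno([[0, 0, 0.0]]))[0] == 0.0

    def test_apoe_effect_size_contribution(self):
        # two copies of the strongest coding risk allele, weight 1.182
        g = make_geno([[2.0]], ids=["rs429358"], alleles=[("C", "T")])
        model = WeightedPRSModel(["rs429358"], [1.182])
        assert model.score(g)[0] == pytest.approx(2.364)

    def test_equals_bruteforce_loop(self, rng):
        d = rng.uniform(0, 2, size=(20, 7))
        w = rng.normal(size=7)
        g = make_geno(d)
        model = WeightedPRSModel(g.variant_ids, w)
        scores = weighted_prs(g, model)
        brute = np.array([sum(w[j] * d[i, j] for j in range(7))
                          for i in range(20)])
        np.testing.assert_allclose(scores, brute, rtol=1e-12)

    def test_linearity_and_permutation_invariance(self, rng):
        d = rng.uniform(0, 2, size=(10, 4))
        g = make_geno(d)
        w = rng.normal(size=4)
        model = WeightedPRSModel(g.variant_ids, w)
        perm = [2, 0, 3, 1]
        model_p = WeightedPRSModel([g.variant_ids[j] for j in perm], w[perm])
        np.testing.assert_allclose(model.score(g), model_p.score(g),
                                   rtol=1e-12)
        half = make_geno(d / 2)
        np.testing.assert_allclose(2 * model.score(half), model.score(g),
                                   rtol=1e-12)

    def test_missing_variant_error(self):
        g = make_geno([[1.0]])
        with pytest.raises(KeyError, match="rs9"):
            WeightedPRSModel(["rs9"], [1.0]).score(g)

    def test_missing_dosage_mean_imputed(self):
        g = make_geno([[0.0], [2.0], [np.nan]])
        model = WeightedPRSModel(["rs1"], [1.0])
        assert model.score(g)[2] == pytest.approx(1.0)


class TestLasso:
    def _sim(self, rng, n=300, p=4):
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        eta = 0.3 + X @ np.concatenate([[0.8, -0.5], np.zeros(p - 2)])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return X, y

    def test_infinite_penalty_limit(self, rng):
        X, y = self._sim(rng)
        betas, _, b0 = _cd_logistic_path(X, np.empty((len(y), 0)), y,
                                         np.array([50.0]), np.zeros(len(y)))
        assert (betas[0] == 0).all()
        assert b0[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())),
                                      abs=1e-8)

    def test_zero_penalty_equals_mle(self, rng):
        X, y = self._sim(rng)
        betas, _, b0 = _cd_logistic_path(X, np.empty((len(y), 0)), y,
                                         np.array([0.0]), np.zeros(len(y)))
        coef, _, ok = logistic_irls(np.column_stack([np.ones(len(y)), X]), y)
        assert ok
        np.testing.assert_allclose(np.concatenate([[b0[0]], betas[0]]),
                                   coef, atol=1e-4)

    def test_matches_statsmodels_on_grid_point(self, rng):
        import statsmodels.api as sm

        X, y = self._sim(rng)
        lam = 0.05
        betas, _, b0 = _cd_logistic_path(X, np.empty((len(y), 0)), y,
                                         np.array([lam]), np.zeros(len(y)))
        alpha = np.array([0.0] + [lam * len(y)] * X.shape[1])
        ref = sm.Logit(y, np.column_stack([np.ones(len(y)), X])) \
            .fit_regularized(method="l1", alpha=alpha, disp=0,
                             trim_mode="off", acc=1e-12)
        np.testing.assert_allclose(np.concatenate([[b0[0]], betas[0]]),
                                   np.asarray(ref.params), atol=2e-4)

    def _cohort(self, seed=3, n=600, p=12):
        from prsnet.simulate import SimSpec, simulate_cohort

        spec = SimSpec(n_samples=n, n_variants=p, seed=seed,
                       additive_effects={0: 0.8, 1: -0.8},
                       liability_noise_sd=0.5)
        return simulate_cohort(spec)

    def test_fit_selects_smallest_lambda(self):
        c = self._cohort()
        model = fit_lasso(c.genotypes, c.phenotypes, seed=0, n_lambda=30)
        lams = [l for l, _, _ in model.cv_path]
        nnz = [k for _, _, k in model.cv_path]
        eligible = [l for l, k in zip(lams, nnz) if k == max(nnz)]
        assert model.lambda_chosen == min(eligible)
        assert model.n_nonzero == max(nnz)

    def test_determinism_and_fold_reuse(self):
        c = self._cohort()
        a = fit_lasso(c.genotypes, c.phenotypes, seed=5, n_lambda=20)
        b = fit_lasso(c.genotypes, c.phenotypes, seed=5, n_lambda=20)
        np.testing.assert_array_equal(a.variant_coefs, b.variant_coefs)
        np.testing.assert_array_equal(a.folds, b.folds)
        d = fit_lasso(c.genotypes, c.phenotypes, seed=5, n_lambda=20,
                      folds=a.folds)
        np.testing.assert_allclose(a.variant_coefs, d.variant_coefs)

    def test_regress_out_mode_runs(self):
        c = self._cohort()
        model = fit_lasso(c.genotypes, c.phenotypes, seed=1, n_lambda=15,
                          covariate_mode="regress-out")
        assert model.covariate_mode == "regress-out"
        assert model.offset_model is not None
        s = model.score(c.genotypes)
        assert len(s) == c.genotypes.n_samples

    def test_degenerate_inputs(self):
        g = make_geno(np.ones((40, 2)))
        p = make_pheno(["AD"] * 20 + ["NC"] * 20)
        with pytest.raises(ValueError, match="constant"):
            fit_lasso(g, p, covariates=[])
        g2 = make_geno(np.tile([[0.0, 1.0]], (40, 1)))
        p_all_case = make_pheno(["AD"] * 40)
        with pytest.raises(ValueError, match="binary|class"):
            fit_lasso(g2, p_all_case, covariates=[])


class TestArchitectures:
    def test_european_widths_scale_with_loci(self):
        model = build_nn("european", n_features=200, n_loci=77)
        assert model.dense_widths == [231, 77, 22, 5, 1]
        kinds = [k for k, _ in model.layer_spec]
        assert kinds[0] == "dropout" and kinds[2] == "dropout"

    def test_chinese_fixed_widths(self):
        model = build_nn("chinese", n_features=37)
        assert model.dense_widths == [50, 30, 10, 5, 1]
        kinds = [k for k, _ in model.layer_spec]
        assert kinds[1] == "dropout" and kinds[3] == "dropout"

    def test_same_seed_identical_init(self):
        a = build_nn("chinese", n_features=10, seed=4)
        b = build_nn("chinese", n_features=10, seed=4)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        c = build_nn("chinese", n_features=10, seed=5)
        assert any(not np.array_equal(wa, wc)
                   for wa, wc in zip(a.weights, c.weights))

    def test_zero_loci_error(self):
        with pytest.raises(ValueError, match="n_loci"):
            build_nn("european", n_features=10, n_loci=0)

    def test_final_width_must_be_one(self):
        with pytest.raises(ValueError, match="width 1"):
            NeuralPRSModel([("dense", 3)], n_features=2)


class TestLearningRateSchedule:
    @pytest.mark.parametrize("step,expected", [
        (0, 0.5),
        (99_999, 0.5),
        (100_000, 0.5 * 0.96),
        (200_000, 0.5 * 0.96**2),
    ])
    def test_staircase(self, step, expected):
        cfg = TrainConfig(lr0=0.5)
        assert lr_at_step(cfg, step) == pytest.approx(expected, rel=1e-12)

    def test_smooth_variant(self):
        cfg = TrainConfig(lr0=0.5, staircase=False)
        assert lr_at_step(cfg, 50_000) == pytest.approx(0.5 * 0.96**0.5)

    def test_negative_step(self):
        with pytest.raises(ValueError):
            lr_at_step(TrainConfig(), -1)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        from prsnet.models.nn import _bce

        rng = np.random.default_rng(0)
        model = NeuralPRSModel([("dense", 4), ("dense", 3), ("dense", 1)],
                               n_features=3, init_seed=2)
        X = rng.normal(size=(5, 3))
        y = (rng.random(5) < 0.5).astype(float)
        di, do, masks = model._forward(X, training=True, rng=rng)
        gw, gb = model._backward(di, do, masks, y)
        eps = 1e-6
        worst = 0.0
        for k, W in enumerate(model.weights):
            for idx in np.ndindex(W.shape):
                orig = W[idx]
                W[idx] = orig + eps
                up = _bce(y, model.scores(X))
                W[idx] = orig - eps
                dn = _bce(y, model.scores(X))
                W[idx] = orig
                worst = max(worst, abs((up - dn) / (2 * eps) - gw[k][idx]))
        assert worst < 1e-5


class TestTraining:
    def test_zero_weight_model_scores_half(self):
        model = NeuralPRSModel([("dense", 1)], n_features=3)
        model.weights = [np.zeros((3, 1))]
        model.biases = [np.zeros(1)]
        np.testing.assert_allclose(model.scores(np.eye(3)), 0.5)

    def test_seed_deterministic_training(self, rng):
        X = rng.normal(size=(120, 6))
        y = (rng.random(120) < 0.5).astype(float)
        final = []
        for _ in range(2):
            m = build_nn("chinese", n_features=6, seed=3)
            train_nn(m, X, y, TrainConfig(epochs=15, batch_size=32, seed=3))
            final.append([w.copy() for w in m.weights])
        for wa, wb in zip(*final):
            np.testing.assert_array_equal(wa, wb)

    def test_monotone_network_is_monotone_in_dosage(self):
        model = NeuralPRSModel([("dense", 1), ("dense", 1)], n_features=1)
        model.weights = [np.array([[2.0]]), np.array([[3.0]])]
        model.biases = [np.zeros(1), np.zeros(1)]
        s = model.scores(np.array([[0.0], [1.0], [2.0]]))
        assert s[0] < s[1] < s[2]

    def test_scoring_is_idempotent(self, rng):
        m = build_nn("chinese", n_features=4, seed=1)
        X = rng.uniform(0, 2, size=(30, 4))
        np.testing.assert_array_equal(m.scores(X), m.scores(X))

    def test_early_stopping_bounds_overrun(self, rng):
        X = rng.normal(size=(300, 5))
        y = (rng.random(300) < 0.5).astype(float)  # pure noise labels
        m = build_nn("chinese", n_features=5, seed=0)
        cfg = TrainConfig(epochs=400, batch_size=64, lr0=0.5, seed=0,
                          patience=20, validation_fraction=0.3)
        hist = train_nn(m, X, y, cfg)
        assert hist.stopped_epoch < 400 - 1
        assert hist.stopped_epoch - hist.best_epoch <= 20 + 1

    def test_divergence_raises_named_epoch(self):
        X = np.full((8, 1), 1.0)
        y = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
        m = NeuralPRSModel([("dense", 1)], n_features=1)
        m.weights = [np.array([[np.nan]])]
        m.biases = [np.zeros(1)]
        with pytest.raises(FloatingPointError, match="epoch"):
            train_nn(m, X, y, TrainConfig(epochs=1, batch_size=8, seed=0),
                     standardize=False)

    def test_save_load_round_trip(self, tmp_path, rng):
        m = build_nn("chinese", n_features=4, seed=6)
        X = rng.uniform(0, 2, size=(60, 4))
        y = (rng.random(60) < 0.5).astype(float)
        train_nn(m, X, y, TrainConfig(epochs=5, batch_size=16, seed=6))
        path = tmp_path / "model.json"
        m.save(path, TrainConfig(epochs=5, batch_size=16, seed=6))
        back = NeuralPRSModel.load(path)
        np.testing.assert_array_equal(back.scores(X), m.scores(X))
        assert back.trained


class TestPenultimate:
    def test_width_five_for_both_reference_architectures(self, rng):
        X = rng.uniform(0, 2, size=(10, 8))
        for kind, kwargs in [("european", {"n_loci": 4}), ("chinese", {})]:
            m = build_nn(kind, n_features=8, **kwargs)
            assert penultimate_outputs(m, X).shape == (10, 5)

    def test_zero_weights_give_half_activation(self):
        m = NeuralPRSModel([("dense", 5), ("dense", 1)], n_features=3)
        m.weights = [np.zeros((3, 5)), np.zeros((5, 1))]
        m.biases = [np.zeros(5), np.zeros(1)]
        np.testing.assert_allclose(m.penultimate(np.eye(3)), 0.5)

    def test_single_layer_model_error(self):
        m = NeuralPRSModel([("dense", 1)], n_features=2)
        with pytest.raises(ValueError, match="penultimate"):
            m.penultimate(np.zeros((1, 2)))


def xor_cohort(seed, n=4000):
    """Two-variant XOR-like liability: carriers of exactly one risk allele
    set are at high risk; marginal effects vanish at carrier frequency 1/2."""
    rng = np.random.default_rng(seed)
    p_carrier_half = 1 - np.sqrt(0.5)
    g = rng.binomial(2, p_carrier_half, size=(n, 2)).astype(float)
    xor = ((g[:, 0] > 0) ^ (g[:, 1] > 0)).astype(float)
    liability = 6.0 * xor
    prob = 1 / (1 + np.exp(-(liability - liability.mean())))
    y = (rng.random(n) < prob).astype(float)
    return g, y


class TestEpistasisAdvantage:
    def test_nn_learns_xor_where_weighted_prs_cannot(self):
        nn_aucs, w_aucs = [], []
        for seed in range(5):
            g, y = xor_cohort(seed)
            idx = np.random.default_rng(100 + seed).permutation(len(y))
            tr, te = idx[:2800], idx[2800:]
            model = build_nn("chinese", n_features=2, dropout_rate=0.0,
                             seed=seed)
            cfg = TrainConfig(epochs=2000, batch_size=256, lr0=0.5, seed=seed)
            train_nn(model, g[tr], y[tr], cfg)
            nn_aucs.append(auroc(nn_score(model, g[te]), y[te]))
            betas = [
                logistic_irls(np.column_stack([np.ones(len(tr)), g[tr, j]]),
                              y[tr])[0][1]
                for j in range(2)
            ]
            w_aucs.append(auroc(g[te] @ np.array(betas), y[te]))
        assert np.mean(nn_aucs) >= 0.9
        assert np.mean(w_aucs) <= 0.55


class TestGraphModel:
    def test_adjacency_extremes(self, rng):
        d = rng.uniform(0, 2, size=(30, 4))
        g = make_geno(d)
        complete = build_graphs(g, np.ones((4, 4)))
        assert complete.n_edges == 4 * 3 // 2
        edgeless = build_graphs(g, np.eye(4))
        assert edgeless.n_edges == 0
        np.testing.assert_allclose(edgeless.a_hat, np.eye(4), atol=1e-7)

    def test_feature_schema_and_normalization(self, rng):
        d = rng.uniform(0, 2, size=(50, 3))
        g = make_geno(d)
        graphs = build_graphs(g, np.eye(3))
        assert graphs.features.shape == (50, 3, 7)  # dosage + 6 annotations
        flat = graphs.features.reshape(-1, 7)
        np.testing.assert_allclose(flat[:, 0].mean(), 0.0, atol=1e-5)

    def test_training_deterministic_and_learns_signal(self):
        # signal aligned with the pooling operator: risk driven by the
        # largest dosage across nodes, which global max pooling can read out
        rng = np.random.default_rng(2)
        n = 600
        d = rng.uniform(0, 2, size=(n, 5))
        mx = d.max(axis=1)
        y = (rng.random(n) < 1 / (1 + np.exp(-(3.0 * (mx - mx.mean()))))
             ).astype(float)
        g = make_geno(d)
        graphs = build_graphs(g, np.eye(5))
        kwargs = dict(hidden_dim=16, classifier_dim=8, max_epochs=200,
                      patience=30, batch_size=64, lr=3e-3, seed=0)
        m1 = train_gnn(graphs, y, **kwargs)
        m2 = train_gnn(graphs, y, **kwargs)
        s1, s2 = gnn_score(m1, graphs), gnn_score(m2, graphs)
        np.testing.assert_array_equal(s1, s2)
        assert auroc(s1, y) > 0.6

    def test_feature_mismatch_error(self, rng):
        d = rng.uniform(0, 2, size=(40, 3))
        g = make_geno(d)
        graphs = build_graphs(g, np.eye(3))
        model = train_gnn(graphs, (rng.random(40) < 0.5).astype(float),
                          hidden_dim=8, classifier_dim=4, max_epochs=3,
                          seed=0)
        bad = build_graphs(g, np.eye(3))
        bad.features = bad.features[:, :, :2]
        with pytest.raises(ValueError, match="schema"):
            gnn_score(model, bad)
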