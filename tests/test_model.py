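"""Feature table, elastic-net INDEX model, hold-out benchmark, ROC averaging."""

import numpy as np
import pandas as pd
import pytest

from cfmethdx.model import (
    ElasticNetLogistic,
    FeatureTable,
    IndexModel,
    SplitScheme,
    average_roc,
    build_feature_table,
    finalize_index_model,
    fit_elastic_net,
    iter_splits,
    lambda_grid,
    predict_index,
    repeated_holdout_benchmark,
    tune_hyperparameters,
    _split_metrics,
)


def gene_pct_frame(n, n_genes=9, rng=None, prefix="S"):
    rng = rng or np.random.default_rng(0)
    idx = [f"{prefix}{i}" for i in range(n)]
    return pd.DataFrame(
        rng.uniform(20, 80, size=(n, n_genes)),
        index=idx,
        columns=[f"G{j}" for j in range(n_genes)],
    )


def toy_table(n=200, shift=0.0, n_noise=9, seed=0):
    """One informative Gaussian feature (class shift in SD units) + noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x0 = rng.normal(0, 1, n) + shift * y
    X = pd.DataFrame(
        np.column_stack([x0] + [rng.normal(0, 1, n) for _ in range(n_noise)]),
        index=[f"S{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(n_noise + 1)],
    )
    return FeatureTable(X=X, y=y, feature_names=list(X.columns))


class TestBuildFeatureTable:
    def test_cohort_shape_and_transform(self):
        n = 78
        pct = gene_pct_frame(n)
        copies = pd.Series(1000.0, index=pct.index)
        labels = pd.Series(["case"] * 38 + ["control"] * 40, index=pct.index)
        t = build_feature_table(pct, copies, labels)
        assert t.X.shape == (78, 10)
        assert t.feature_names[-1] == "log10_copies"
        assert np.allclose(t.X["log10_copies"], 3.0)
        assert t.y.sum() == 38
        assert t.transforms["log10_copies"] == "log10"

    def test_sample_missing_too_many_features_excluded(self):
        pct = gene_pct_frame(6, n_genes=9)
        pct.iloc[0, :5] = np.nan
        copies = pd.Series(100.0, index=pct.index)
        labels = pd.Series(["case", "case", "case", "control", "control", "control"],
                           index=pct.index)
        with pytest.warns(UserWarning):
            t = build_feature_table(pct, copies, labels)
        assert t.X.shape[0] == 5

    def test_unlabelled_sample_rejected(self):
        pct = gene_pct_frame(4)
        copies = pd.Series(10.0, index=pct.index)
        labels = pd.Series(["case"], index=pct.index[:1])
        with pytest.raises(ValueError):
            build_feature_table(pct, copies, labels)


class TestElasticNet:
    def test_zero_penalty_matches_unpenalized_logistic_oracle(self):
        import statsmodels.api as sm

        table = toy_table(n=200, shift=1.0, n_noise=4, seed=5)
        X = table.X.to_numpy()
        model = fit_elastic_net(X, table.y, lam=0.0)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        sm_fit = sm.Logit(table.y, sm.add_constant(Z)).fit(disp=0, tol=1e-12)
        assert np.allclose(model.intercept_, sm_fit.params[0], atol=1e-4)
        assert np.allclose(model.coef_, sm_fit.params[1:], atol=1e-4)

    def test_total_shrinkage_leaves_only_class_balance_intercept(self):
        table = toy_table(n=120, shift=2.0, seed=1)
        y = np.concatenate([np.zeros(80, int), np.ones(40, int)])
        model = ElasticNetLogistic(alpha_mix=0.5, lam=1e4).fit(table.X.iloc[:120], y)
        assert np.allclose(model.coef_, 0.0, atol=1e-9)
        assert model.intercept_ == pytest.approx(np.log(40 / 80), abs=1e-6)

    def test_l1_produces_exact_zeros_with_sparse_signal(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(0, 1, (n, 10))
            X[:, 0] += 1.5 * y
            X[:, 1] -= 1.5 * y
            lam = lambda_grid(X, y, alpha_mix=1.0, n_lambda=10)[2]  # strong penalty
            model = ElasticNetLogistic(alpha_mix=1.0, lam=lam).fit(X, y)
            hits += np.sum(model.coef_ == 0.0) >= 6
        assert hits == 20

    def test_matches_glmnet_oracle(self, tmp_path):
        # independent oracle: R glmnet on the same standardized design
        import subprocess

        rng = np.random.default_rng(12)
        n = 150
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 5))
        X[:, 0] += 1.2 * y
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        lam, alpha = 0.05, 0.5
        np.savetxt(tmp_path / "z.csv", Z, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        script = tmp_path / "fit.R"
        script.write_text(
            'z <- as.matrix(read.csv("%s", header=FALSE))\n'
            'y <- scan("%s")\n'
            "suppressMessages(library(glmnet))\n"
            "f <- glmnet(z, y, family='binomial', alpha=%f, lambda=%f,\n"
            "            standardize=FALSE, thresh=1e-14)\n"
            'cat(c(as.numeric(f$a0), as.numeric(f$beta)), sep="\\n")\n'
            % (tmp_path / "z.csv", tmp_path / "y.csv", alpha, lam)
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        oracle = np.array([float(v) for v in out.stdout.split()])
        model = ElasticNetLogistic(alpha, lam, tol=1e-12).fit(X, y)
        assert model.intercept_ == pytest.approx(oracle[0], abs=2e-4)
        assert np.allclose(model.coef_, oracle[1:], atol=2e-4)

    def test_fit_is_deterministic(self):
        table = toy_table(n=100, shift=1.0, seed=2)
        a = fit_elastic_net(table.X.to_numpy(), table.y, 0.5, 0.01)
        b = fit_elastic_net(table.X.to_numpy(), table.y, 0.5, 0.01)
        assert np.array_equal(a.coef_, b.coef_) and a.intercept_ == b.intercept_

    def test_single_class_fold_rejected(self):
        with pytest.raises(ValueError):
            ElasticNetLogistic().fit(np.random.default_rng(0).normal(size=(10, 2)),
                                     np.zeros(10, int))

    def test_raw_scale_coefficients_reproduce_scores(self):
        table = toy_table(n=150, shift=1.0, seed=3)
        X = table.X.to_numpy()
        model = fit_elastic_net(X, table.y, 0.5, 0.01)
        raw_scores = X @ model.coef_raw_ + model.intercept_raw_
        assert np.allclose(raw_scores, model.decision_function(X), atol=1e-10)

    def test_parameter_recovery_unpenalized_at_large_n(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n = 2000
        X = rng.normal(0, 1, (n, 3))
        beta = np.array([1.0, -0.5, 0.0])
        p = 1 / (1 + np.exp(-(0.3 + X @ beta)))
        y = rng.binomial(1, p)
        model = fit_elastic_net(X, y, lam=0.0)
        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        for b_hat, b_true, se in zip(model.coef_raw_, beta, sm_fit.bse[1:]):
            assert abs(b_hat - b_true) < 3 * se


class TestTuning:
    def test_single_point_grid_returned(self):
        table = toy_table(n=60, shift=1.0, seed=4)
        a, l, cv = tune_hyperparameters(
            table.X.to_numpy(), table.y, alphas=[0.5], n_lambda=1, k=3
        )
        assert a == 0.5 and len(cv) == 1 and l == cv.lam[0]

    def test_pure_noise_cv_auc_near_chance(self):
        aucs = []
        for seed in range(20):
            table = toy_table(n=80, shift=0.0, seed=seed)
            _, _, cv = tune_hyperparameters(
                table.X.to_numpy(), table.y, alphas=(0.0, 0.5, 1.0),
                n_lambda=5, k=3, seed=seed,
            )
            aucs.append(cv.mean_auc.max())
        assert 0.35 <= np.median(aucs) <= 0.70

    def test_strong_signal_cv_auc_near_bayes(self):
        from scipy.stats import norm

        # two features each shifted d=2: Bayes AUC = Phi(sqrt(2)*sqrt(2))
        rng = np.random.default_rng(0)
        n = 400
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 4))
        X[:, 0] += 2.0 * y
        X[:, 1] += 2.0 * y
        a, l, cv = tune_hyperparameters(X, y, alphas=(0.0, 0.5, 1.0), n_lambda=5, k=5)
        bayes = norm.cdf(np.sqrt(8) / np.sqrt(2))
        assert abs(cv.mean_auc.max() - bayes) < 0.05

    def test_k_reduced_when_class_too_small(self):
        table = toy_table(n=8, shift=1.0, n_noise=1, seed=0)
        with pytest.warns(UserWarning):
            tune_hyperparameters(table.X.to_numpy(), table.y,
                                 alphas=[0.5], n_lambda=2, k=5)


class TestSplitsAndBenchmark:
    def test_splits_are_seed_deterministic_and_stratified(self):
        table = toy_table(n=40, seed=0)
        scheme = SplitScheme(n_splits=10, seed=3)
        s1 = list(iter_splits(table, scheme))
        s2 = list(iter_splits(table, scheme))
        assert s1 == s2
        y = pd.Series(table.y, index=table.sample_ids)
        for train, test in s1:
            assert y[train].sum() >= 2 and (1 - y[train]).sum() >= 2
            assert y[test].sum() >= 1 and (1 - y[test]).sum() >= 1

    def test_row_order_does_not_change_splits(self):
        table = toy_table(n=40, seed=0)
        Xs = table.X.sample(frac=1, random_state=7)
        ys = pd.Series(table.y, index=table.X.index)[Xs.index].to_numpy()
        shuffled = FeatureTable(X=Xs, y=ys, feature_names=table.feature_names)
        a = list(iter_splits(table, SplitScheme(n_splits=5, seed=1)))
        b = list(iter_splits(shuffled, SplitScheme(n_splits=5, seed=1)))
        assert a == b

    def test_perfect_separator_gives_auc_one(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {"sep": y * 10.0 + rng.normal(0, 0.1, n), "noise": rng.normal(0, 1, n)},
            index=[f"S{i}" for i in range(n)],
        )
        table = FeatureTable(X=X, y=y, feature_names=list(X.columns))
        res = repeated_holdout_benchmark(
            table, SplitScheme(n_splits=30, seed=2),
            families=["elastic_net"], enet_params=(0.5, 0.01),
        )["elastic_net"]
        assert res.summary["mean_auc"] == 1.0
        assert res.summary["mean_accuracy"] >= 0.98

    def test_metric_consistency_per_split(self):
        table = toy_table(n=80, shift=1.0, seed=6)
        res = repeated_holdout_benchmark(
            table, SplitScheme(n_splits=25, seed=4),
            families=["elastic_net"], enet_params=(0.5, 0.05),
        )["elastic_net"]
        # accuracy = prevalence*sens + (1-prevalence)*spec on each test split
        splits = list(iter_splits(table, SplitScheme(n_splits=25, seed=4)))
        for i, (_, test_ids) in enumerate(splits):
            y = pd.Series(table.y, index=table.sample_ids)[test_ids]
            prev = y.mean()
            assert res.accuracy[i] == pytest.approx(
                prev * res.sensitivity[i] + (1 - prev) * res.specificity[i], abs=1e-12
            )

    def test_all_five_families_run(self):
        table = toy_table(n=40, shift=2.0, seed=7)
        res = repeated_holdout_benchmark(
            table, SplitScheme(n_splits=3, seed=0),
            enet_params=(0.5, 0.05),
        )
        assert set(res) == {
            "decision_tree", "logistic", "svm_rbf", "random_forest", "elastic_net"
        }
        for r in res.values():
            assert 0.0 <= r.summary["mean_auc"] <= 1.0
            assert 0.0 <= r.mean_tpr.min() and r.mean_tpr.max() <= 1.0
            assert (np.diff(r.mean_tpr) >= -1e-12).all()  # monotone averaged ROC

    def test_auc_invariances(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(0, 1, 50)
        auc, *_ = _split_metrics(y, s, (s > 0).astype(int))
        auc_mono, *_ = _split_metrics(y, np.exp(3 * s), (s > 0).astype(int))
        auc_neg, *_ = _split_metrics(y, -s, (s > 0).astype(int))
        assert auc == pytest.approx(auc_mono, abs=1e-12)
        assert auc_neg == pytest.approx(1 - auc, abs=1e-12)

    def test_leakage_guard_test_outlier_cannot_affect_scaling(self):
        table = toy_table(n=50, shift=1.0, seed=8)
        Xtr = table.X.iloc[:40].to_numpy()
        ytr = table.y[:40]
        model = fit_elastic_net(Xtr, ytr, 0.5, 0.01)
        Xte = table.X.iloc[40:].to_numpy().copy()
        base = model.decision_function(Xte)
        Xte_outlier = Xte.copy()
        Xte_outlier[0] = 1e6  # extreme test-only outlier
        with_outlier = model.decision_function(Xte_outlier)
        assert np.allclose(base[1:], with_outlier[1:], atol=1e-12)
        assert np.array_equal(model.means_, fit_elastic_net(Xtr, ytr, 0.5, 0.01).means_)


class TestAverageRoc:
    def test_identical_splits_idempotent(self, rng):
        y = np.array([0, 0, 1, 1, 0, 1])
        s = rng.normal(0, 1, 6)
        grid, single = average_roc([(y, s)])
        _, triple = average_roc([(y, s)] * 3)
        assert np.allclose(single, triple)

    def test_perfect_scores_give_unit_area(self):
        y = np.array([0, 1, 0, 1])
        s = y.astype(float)
        grid, tpr = average_roc([(y, s)])
        assert np.trapezoid(tpr, grid) == pytest.approx(1.0)
        assert tpr[1:].min() == 1.0

    def test_random_scores_concentrate_on_diagonal(self, rng):
        pairs = []
        for _ in range(200):
            y = np.repeat([0, 1], 20)
            pairs.append((y, rng.normal(0, 1, 40)))
        grid, tpr = average_roc(pairs)
        assert np.max(np.abs(tpr - grid)) < 0.05


class TestIndexModel:
    def make_model(self):
        table = toy_table(n=100, shift=1.5, n_noise=2, seed=9)
        return finalize_index_model(table, alpha_mix=0.5, lam=0.01), table

    def test_index_is_linear_combination(self):
        model = IndexModel(
            feature_names=["a", "b", "c"], betas=[0, 0, 0], intercept=0.0,
            betas_raw=[1.0, 0.0, 0.0], intercept_raw=0.0,
            means=[0, 0, 0], scales=[1, 1, 1], alpha_mix=0.5, lam=0.1,
        )
        index, prob, status = predict_index(model, {"a": 2.5, "b": 9, "c": -1})
        assert index == 2.5
        assert prob == pytest.approx(1 / (1 + np.exp(-2.5)), abs=1e-12)

    def test_boundary_probability_is_control(self):
        model = IndexModel(
            feature_names=["a"], betas=[0.0], intercept=0.0,
            betas_raw=[0.0], intercept_raw=0.0, means=[0], scales=[1],
            alpha_mix=0.5, lam=0.1,
        )
        index, prob, status = predict_index(model, {"a": 123.0})
        assert (index, prob, status) == (0.0, 0.5, "control")

    def test_missing_feature_named_in_error(self):
        model, _ = self.make_model()
        with pytest.raises(KeyError, match="f1"):
            predict_index(model, {"f0": 1.0, "f2": 2.0})

    def test_serialization_round_trip_is_bit_exact(self, tmp_path, rng):
        model, table = self.make_model()
        path = model.save(tmp_path / "model.json")
        loaded = IndexModel.load(path)
        for _ in range(100):
            feats = {n: float(rng.normal()) for n in model.feature_names}
            assert predict_index(model, feats) == predict_index(loaded, feats)

    def test_hand_computed_three_feature_dot_product(self):
        model = IndexModel(
            feature_names=["x", "y", "z"], betas=[0, 0, 0], intercept=0.0,
            betas_raw=[0.5, -2.0, 0.25], intercept_raw=1.0,
            means=[0, 0, 0], scales=[1, 1, 1], alpha_mix=0.0, lam=0.0,
        )
        index, _, _ = predict_index(model, {"x": 2.0, "y": 1.5, "z": 4.0})
        assert index == pytest.approx(1.0 + 1.0 - 3.0 + 1.0, abs=1e-12)
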