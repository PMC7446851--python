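"""Model families, chain-grouped protocol and the PCC metric."""

import math

import numpy as np
import pytest

from rnaflex.features import Dataset, FeatureConfig
from rnaflex.learning import (
    ModelSpec,
    SearchGrid,
    assert_no_chain_leakage,
    cross_validate,
    evaluate,
    grid_search,
    make_cv_folds,
    model_from_preset,
    pcc,
    split_chains,
    train_model,
)


def _toy_dataset(n_chains=6, per_chain=8, p=5, seed=0, signal=True):
    """Linear-signal dataset with chain labels, for protocol tests."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=p)
    X, y, labels, ids = [], [], [], []
    for c in range(n_chains):
        Xc = rng.normal(size=(per_chain, p))
        yc = Xc @ w + 0.1 * rng.normal(size=per_chain) if signal else rng.normal(size=per_chain)
        X.append(Xc)
        y.append(yc)
        labels += [f"ch{c}"] * per_chain
        ids += [(f"ch{c}", i) for i in range(per_chain)]
    cfg = FeatureConfig(cutoff=5, fe_ratio=0.5, bin_size=0.5, elements=("P",), dims=(0,))
    return Dataset(np.vstack(X), np.concatenate(y), np.array(labels), ids, cfg)


class TestSplits:
    def test_four_chains_three_one(self):
        train, test = split_chains(list("ABCD"), seed=0)
        assert len(train) == 3 and len(test) == 1

    def test_reproducible_and_partition(self):
        chains = [f"c{i}" for i in range(9)]
        a = split_chains(chains, seed=5)
        b = split_chains(chains, seed=5)
        assert a == b
        train, test = a
        assert sorted(train + test) == sorted(chains)
        assert not set(train) & set(test)

    def test_too_few_chains(self):
        with pytest.raises(ValueError):
            split_chains(["only"], seed=0)

    def test_at_least_one_test_chain(self):
        train, test = split_chains(list("AB"), train_frac=0.99, seed=0)
        assert len(test) == 1


class TestFolds:
    def test_even_folds(self):
        folds = make_cv_folds([f"c{i}" for i in range(10)], k=5, seed=1)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_uneven_folds(self):
        folds = make_cv_folds([f"c{i}" for i in range(11)], k=5, seed=1)
        assert sorted((len(f) for f in folds), reverse=True) == [3, 2, 2, 2, 2]

    def test_folds_partition_exactly(self):
        chains = [f"c{i}" for i in range(13)]
        folds = make_cv_folds(chains, k=5, seed=2)
        flat = [c for f in folds for c in f]
        assert sorted(flat) == sorted(chains)

    def test_fewer_chains_than_folds(self):
        with pytest.raises(ValueError):
            make_cv_folds(["a", "b"], k=5, seed=0)


class TestPCC:
    def test_perfect(self):
        assert pcc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_antiperfect(self):
        assert pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # 6 / sqrt(45) = 0.894427
        assert pcc([1, 2, 3, 4], [1, 2, 2, 5]) == pytest.approx(6 / math.sqrt(45))

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            pcc([1, 2, 3], [5, 5, 5])

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(0)
        y, yh = rng.normal(size=30), rng.normal(size=30)
        assert pcc(y, 3.2 * yh + 7) == pytest.approx(pcc(y, yh), abs=1e-12)


class TestTrainModel:
    def test_ridge_huge_alpha_predicts_mean(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(20, 4)), rng.normal(size=20)
        model = train_model(ModelSpec("ridge", {"alpha": 1e12}), X, y)
        np.testing.assert_allclose(model.predict(X), np.full(20, y.mean()), atol=1e-4)

    def test_ridge_alpha_zero_equals_ols_normal_equations(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(5, 3)), rng.normal(size=5)
        model = train_model(ModelSpec("ridge", {"alpha": 0.0}), X, y)
        # independent oracle: solve the normal equations with an intercept
        A = np.hstack([np.ones((5, 1)), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(model.predict(X), A @ beta, atol=1e-8)

    def test_lasso_huge_alpha_intercept_only(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(20, 4)), rng.normal(size=20)
        model = train_model(ModelSpec("lasso", {"alpha": 1e6}), X, y)
        preds = model.predict(X)
        assert np.allclose(preds, preds[0])

    @pytest.mark.parametrize("family", ["rf", "xgboost", "svr", "ann"])
    def test_nonlinear_families_fit_and_predict(self, family):
        ds = _toy_dataset(seed=4)
        params = {
            "rf": {"n_trees": 30, "min_samples_leaf": 2},
            "xgboost": {"n_trees": 30, "max_depth": 3},
            "svr": {"gamma": 0.1, "C": 10.0, "epsilon": 0.01},
            "ann": {"n_hidden_layers": 2, "nodes_per_layer": 32, "epochs": 60,
                    "dropout": 0.1},
        }[family]
        model = train_model(ModelSpec(family, params, seed=0), ds.X, ds.y)
        preds = model.predict(ds.X)
        assert np.isfinite(preds).all()
        assert pcc(ds.y, preds) > 0.5  # in-sample fit on an easy linear signal

    @pytest.mark.parametrize("family", ["rf", "xgboost", "ann"])
    def test_stochastic_families_deterministic_given_seed(self, family):
        ds = _toy_dataset(seed=5)
        params = {"rf": {"n_trees": 20}, "xgboost": {"n_trees": 20},
                  "ann": {"n_hidden_layers": 1, "nodes_per_layer": 8, "epochs": 3}}[family]
        a = train_model(ModelSpec(family, params, seed=7), ds.X, ds.y).predict(ds.X)
        b = train_model(ModelSpec(family, params, seed=7), ds.X, ds.y).predict(ds.X)
        np.testing.assert_array_equal(a, b)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("gbm")

    def test_presets_complete(self):
        for preset in ("esph-single", "esph-cnop"):
            for family in ("ridge", "lasso", "rf", "xgboost", "svr", "ann"):
                spec = model_from_preset(family, preset)
                assert spec.params


class TestCrossValidate:
    def test_out_of_fold_predictions_never_see_own_chain(self):
        ds = _toy_dataset(n_chains=10, seed=6)
        spec = ModelSpec("ridge", {"alpha": 1.0})
        score, preds = cross_validate(spec, ds, k=5, seed=3)
        folds = make_cv_folds(ds.chains, k=5, seed=3)
        for fold in folds:
            held = set(fold)
            mask = np.array([c in held for c in ds.chain_labels])
            ref = train_model(spec, ds.X[~mask], ds.y[~mask]).predict(ds.X[mask])
            np.testing.assert_allclose(preds[mask], ref, atol=1e-12)

    def test_pooled_score_matches_predictions(self):
        ds = _toy_dataset(n_chains=8, seed=7)
        score, preds = cross_validate(ModelSpec("ridge", {"alpha": 1.0}), ds, seed=1)
        assert score == pytest.approx(pcc(ds.y, preds))


class TestGridSearch:
    def test_single_cell_grid_returns_its_cv_score(self):
        ds = _toy_dataset(n_chains=8, seed=8)
        grid = SearchGrid(cutoffs=(5.0,), fe_ratios=(0.5,), bin_sizes=(0.5,),
                          model_params=({"alpha": 1.0},))
        base = ds.config
        fc, spec, best, table = grid_search(lambda _: ds, grid, "ridge",
                                            base_config=base, seed=2)
        ref, _ = cross_validate(ModelSpec("ridge", {"alpha": 1.0}, seed=2), ds, seed=2)
        assert best == pytest.approx(ref)
        assert len(table) == 1

    def test_argmax_of_score_table(self):
        ds = _toy_dataset(n_chains=8, seed=9)
        grid = SearchGrid(cutoffs=(5.0,), fe_ratios=(0.5,), bin_sizes=(0.5,),
                          model_params=({"alpha": 0.1}, {"alpha": 1e9}))
        fc, spec, best, table = grid_search(lambda _: ds, grid, "ridge",
                                            base_config=ds.config, seed=2)
        assert spec.params == {"alpha": 0.1}  # the absurdly shrunk model loses
        assert best == pytest.approx(table["cv_pcc"].max())

    def test_adding_strictly_worse_duplicate_keeps_argmax(self):
        ds = _toy_dataset(n_chains=8, seed=9)
        small = SearchGrid(cutoffs=(5.0,), fe_ratios=(0.5,), bin_sizes=(0.5,),
                           model_params=({"alpha": 0.1},))
        bigger = SearchGrid(cutoffs=(5.0,), fe_ratios=(0.5,), bin_sizes=(0.5,),
                            model_params=({"alpha": 0.1}, {"alpha": 1e9}))
        _, spec_a, best_a, _ = grid_search(lambda _: ds, small, "ridge",
                                           base_config=ds.config, seed=2)
        _, spec_b, best_b, _ = grid_search(lambda _: ds, bigger, "ridge",
                                           base_config=ds.config, seed=2)
        assert spec_a.params == spec_b.params
        assert best_a == pytest.approx(best_b)


class _Oracle:
    """Stub predictor returning a fixed vector."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def predict(self, X):
        return self.values[: len(X)]


class TestEvaluate:
    def test_perfect_predictor_scores_one(self):
        ds = _toy_dataset(n_chains=4, seed=10)
        res = evaluate(_Oracle(ds.y), ds)
        assert res.pcc == pytest.approx(1.0)

    def test_per_chain_count(self):
        ds = _toy_dataset(n_chains=5, per_chain=4, seed=11)
        res = evaluate(_Oracle(ds.y + 0.01), ds)
        assert len(res.per_chain_pcc) == 5

    def test_pooled_differs_from_mean_of_per_chain(self):
        # two chains, each predicted perfectly up to an opposing offset:
        # per-chain PCCs are 1.0 but the pooled correlation is degraded
        cfg = FeatureConfig(cutoff=5, fe_ratio=0.5, bin_size=0.5,
                            elements=("P",), dims=(0,))
        y = np.array([0.0, 1.0, 10.0, 11.0])
        preds = np.array([10.0, 11.0, 0.0, 1.0])
        ds = Dataset(np.zeros((4, cfg.n_features)), y,
                     np.array(["a", "a", "b", "b"]), [("a", 1), ("a", 2), ("b", 1), ("b", 2)], cfg)
        res = evaluate(_Oracle(preds), ds)
        per_chain_mean = np.mean(list(res.per_chain_pcc.values()))
        assert per_chain_mean == pytest.approx(1.0)
        assert res.pcc < 0.0  # pooled sees the opposing offsets

    def test_empty_test_set_rejected(self):
        ds = _toy_dataset(n_chains=2, seed=12)
        empty = ds.subset_chains([])
        with pytest.raises(ValueError, match="empty"):
            evaluate(_Oracle(ds.y), empty)


class TestLeakageGuard:
    def test_overlap_detected(self):
        with pytest.raises(ValueError, match="leakage"):
            assert_no_chain_leakage(["a", "b"], ["b", "c"])

    def test_disjoint_ok(self):
        assert_no_chain_leakage(["a"], ["b"]) is None
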