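"""Cross-validation, tuning, the metric suite, and prediction."""

import numpy as np
import pytest

from premir import (
    auprc_step,
    cross_validate,
    evaluate,
    evaluate_scores,
    metrics_from_counts,
    predict,
    roc_auc_trapezoid,
    train_model,
    tune,
    tuned_presets,
)
from premir.classify import HyperparamSpace

import _oracles


def _separable(n=60, d=5, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, size=(n, d)), rng.normal(gap, 1, size=(n, d))]
    )
    y = np.array([0] * n + [1] * n)
    return X, y


class TestCrossValidate:
    def test_perfectly_separable_scores_one(self):
        X, y = _separable()
        mean, folds = cross_validate("logr", {"C": 10, "solver": "lbfgs"}, X, y)
        assert mean == 1.0
        assert len(folds) == 10

    def test_permuted_labels_score_near_half(self):
        rng = np.random.default_rng(123)
        X, y = _separable(n=100)
        y_perm = rng.permutation(y)
        mean, _ = cross_validate("knn", {"n_neighbors": 5}, X, y_perm, seed=1)
        assert 0.4 <= mean <= 0.6

    def test_same_seed_same_result(self):
        X, y = _separable(n=30, gap=1.0, seed=2)
        a, fa = cross_validate("knn", {"n_neighbors": 3}, X, y, seed=7)
        b, fb = cross_validate("knn", {"n_neighbors": 3}, X, y, seed=7)
        assert a == b and fa == fb

    def test_too_few_rows_rejected(self):
        X, y = _separable(n=4)
        with pytest.raises(ValueError, match="fold"):
            cross_validate("knn", {"n_neighbors": 1}, X, y, folds=10)


class TestTune:
    def test_single_configuration_space_returned_unchanged(self):
        X, y = _separable(n=20)
        space = HyperparamSpace("knn", {"n_neighbors": [3]})
        res = tune("knn", X, y, space=space, n_random=3, folds=5, seed=0)
        assert res.best_params == {"n_neighbors": 3}

    def test_monotone_parameter_recovers_exhaustive_optimum(self):
        # accuracy is monotone in C for an underfit linear problem: the
        # coordinate sweep must find the same optimum as an exhaustive sweep
        X, y = _separable(n=25, gap=0.8, seed=3)
        grid = [0.0001, 0.001, 0.01, 1.0]
        space = HyperparamSpace("logr", {"C": grid, "solver": ["lbfgs"]})
        res = tune("logr", X, y, space=space, n_random=2, folds=5, seed=0)
        exhaustive = {
            c: cross_validate("logr", {"C": c, "solver": "lbfgs"}, X, y, folds=5, seed=0)[0]
            for c in grid
        }
        best_score = max(exhaustive.values())
        assert res.best_score == best_score
        # tie-break toward the simplest C attaining the optimum
        simplest = next(c for c in grid if exhaustive[c] == best_score)
        assert res.best_params["C"] == simplest

    def test_trace_bookkeeping(self):
        X, y = _separable(n=20)
        space = HyperparamSpace("knn", {"n_neighbors": [1, 3, 5]})
        res = tune("knn", X, y, space=space, n_random=4, folds=5, seed=1)
        # every evaluated configuration appears exactly once (cached)
        seen = [tuple(sorted(p.items())) for p, _ in res.trace]
        assert len(seen) == len(set(seen))
        assert len(res.trace) <= 3  # grid has only 3 distinct configs


class TestMetrics:
    def test_table_confusion_rows_reproduce_published_metrics(self):
        rf = metrics_from_counts(tp=449, tn=94136, fp=22094, fn=15)
        assert rf.acc == pytest.approx(0.810539, abs=1e-4)
        assert rf.mcc == pytest.approx(0.12395, abs=1e-4)
        assert rf.f1 == pytest.approx(0.039032, abs=1e-4)
        svm = metrics_from_counts(tp=415, tn=111147, fp=5083, fn=49)
        assert svm.acc == pytest.approx(0.956022, abs=1e-4)
        assert svm.mcc == pytest.approx(0.252656, abs=1e-4)
        assert svm.precision == pytest.approx(0.075482, abs=1e-4)

    def test_perfect_predictions(self):
        r = metrics_from_counts(tp=10, tn=10, fp=0, fn=0)
        assert (r.acc, r.sn, r.sp, r.precision, r.f1, r.mcc) == (1, 1, 1, 1, 1, 1)

    def test_no_association_gives_zero_mcc(self):
        assert metrics_from_counts(25, 25, 25, 25).mcc == 0

    def test_zero_denominators_give_zero(self):
        r = metrics_from_counts(tp=0, tn=50, fp=0, fn=10)
        assert r.precision == 0 and r.f1 == 0 and r.mcc == 0

    def test_agrees_with_hand_computation_on_random_matrices(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 500, size=4)
            r = metrics_from_counts(int(tp), int(tn), int(fp), int(fn))
            expect = _oracles.confusion_metrics(int(tp), int(tn), int(fp), int(fn))
            assert r.acc == pytest.approx(expect["acc"], abs=1e-6)
            assert r.sn == pytest.approx(expect["sn"], abs=1e-6)
            assert r.sp == pytest.approx(expect["sp"], abs=1e-6)
            assert r.precision == pytest.approx(expect["precision"], abs=1e-6)
            assert r.f1 == pytest.approx(expect["f1"], abs=1e-6)
            assert r.mcc == pytest.approx(expect["mcc"], abs=1e-6)

    def test_mcc_invariant_under_class_swap(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 100, size=4))
            assert metrics_from_counts(tp, tn, fp, fn).mcc == pytest.approx(
                metrics_from_counts(tn, tp, fn, fp).mcc
            )


class TestAuc:
    def test_binary_scores_collapse_to_single_trapezoid(self, rng):
        # for 0/1 scores, AUC = (SN + SP) / 2 exactly
        for _ in range(50):
            y = rng.integers(0, 2, size=40)
            if len(set(y)) < 2:
                continue
            scores = rng.integers(0, 2, size=40).astype(float)
            rep = evaluate_scores(y, scores)
            assert rep.auc == pytest.approx((rep.sn + rep.sp) / 2, abs=1e-12)

    def test_matches_sklearn_on_continuous_scores(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        for _ in range(25):
            y = rng.integers(0, 2, size=60)
            if len(set(y)) < 2:
                continue
            s = rng.random(60)
            assert roc_auc_trapezoid(y, s) == pytest.approx(roc_auc_score(y, s))
            assert auprc_step(y, s) == pytest.approx(average_precision_score(y, s))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_scores([0, 1], [0.5])


class TestTrainEvaluatePredict:
    def test_separable_problem_evaluates_cleanly(self):
        X, y = _separable(seed=5)
        model = train_model("rf", {"n_estimators": 50}, X[::2], y[::2], seed=0)
        rep = evaluate(model, X[1::2], y[1::2])
        assert rep.acc > 0.95
        assert 0 <= rep.auprc <= 1

    def test_memorization_sanity_and_order(self, small_fixtures):
        from premir import default_manifest, featurize_many, fit_scaler

        pairs = [(r, s) for r, s, _ in small_fixtures]
        y = np.array([l for _, _, l in small_fixtures])
        table = featurize_many(pairs)
        X = table[default_manifest().names].to_numpy()
        scaler = fit_scaler(X)
        model = train_model(
            "rf", {"n_estimators": 100}, scaler.transform(X), y, scaler=scaler
        )
        out = predict(model, pairs)
        assert [rid for rid, _, _ in out] == [r.id for r, _ in pairs]
        # overfit RF must recall its own training positives
        for (rid, label, prob), (_, _, truth) in zip(out, small_fixtures):
            if truth == 1:
                assert prob > 0.5 and label == 1

    def test_identical_records_identical_outputs(self, small_fixtures):
        from premir import default_manifest, featurize_many, fit_scaler

        pairs = [(r, s) for r, s, _ in small_fixtures]
        y = np.array([l for _, _, l in small_fixtures])
        table = featurize_many(pairs)
        X = table[default_manifest().names].to_numpy()
        scaler = fit_scaler(X)
        model = train_model("knn", {"n_neighbors": 3}, scaler.transform(X), y, scaler=scaler)
        twice = predict(model, [pairs[0], pairs[0]])
        assert twice[0][1:] == twice[1][1:]

    def test_manifest_mismatch_rejected(self, small_fixtures):
        X, y = _separable(n=20, d=93)
        model = train_model("knn", {"n_neighbors": 3}, X, y)
        model.manifest_version = "0.0-other"
        with pytest.raises(ValueError, match="manifest"):
            predict(model, [(small_fixtures[0][0], small_fixtures[0][1])])


class TestPresets:
    def test_published_parameter_sets(self):
        presets = tuned_presets()
        algo, p = presets["svm_smote"]
        assert (algo, p["C"], p["kernel"], p["gamma"]) == ("svm", 10, "rbf", 0.01)
        algo, p = presets["rf_smote"]
        assert p["n_estimators"] == 1600 and p["max_depth"] == 30
        assert p["bootstrap"] is False
        assert p["min_samples_leaf"] == 1 and p["min_samples_split"] == 2
        algo, p = presets["knn_nm"]
        assert (p["metric"], p["n_neighbors"]) == ("euclidean", 7)
        algo, p = presets["logr_smote"]
        assert (p["C"], p["solver"]) == (70, "newton-cg")
        assert len([k for k in presets if not k.startswith("insect")]) == 12

    def test_presets_instantiate(self):
        from premir import make_estimator

        for name, (algo, params) in tuned_presets().items():
            est = make_estimator(algo, params, seed=0)
            assert est is not None
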