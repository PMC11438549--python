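import json

import numpy as np
import pytest

from pepforge.partition import stratified_kfold
from pepforge.train import (
    TrainingError,
    default_search_space,
    fit_ensemble,
    load_model,
    optimize_algorithm,
    save_model,
)


def _folds(labels, k=5, seed=0):
    return stratified_kfold(set(labels), labels, k=k, seed=seed)


@pytest.fixture(scope="module")
def fitted_ensemble(separable_vectors):
    vectors, labels = separable_vectors
    folds = _folds(labels, k=5)
    configs = {"knn": {"n_neighbors": 3, "weights": "uniform"},
               "rfc": {"n_estimators": 50, "max_depth": 4, "min_samples_leaf": 1}}
    return fit_ensemble(vectors, labels, folds, configs,
                        backend_name="onehot", seed=0), vectors, labels


class TestOptimize:
    def test_separable_data_reaches_high_cv_mcc(self, separable_vectors):
        vectors, labels = separable_vectors
        folds = _folds(labels, k=5)
        space = default_search_space(("knn",), n_trials=5, seed=0)
        result = optimize_algorithm(vectors, labels, folds, "knn", space)
        assert result.best_score >= 0.9

    def test_budget_one_returns_single_trial(self, separable_vectors):
        vectors, labels = separable_vectors
        folds = _folds(labels, k=5)
        space = default_search_space(("knn",), n_trials=1, seed=4)
        result = optimize_algorithm(vectors, labels, folds, "knn", space)
        assert len(result.trace) == 1
        assert result.best_params == result.trace[0]["params"]

    def test_trace_records_every_trial_and_is_seed_reproducible(
        self, separable_vectors
    ):
        vectors, labels = separable_vectors
        folds = _folds(labels, k=3)
        space = default_search_space(("rfc",), n_trials=6, seed=9, sampler="gp")
        r1 = optimize_algorithm(vectors, labels, folds, "rfc", space)
        r2 = optimize_algorithm(vectors, labels, folds, "rfc", space)
        assert len(r1.trace) == 6
        assert r1.trace == r2.trace
        assert r1.best_params == r2.best_params

    def test_sampled_configs_lie_in_declared_domain(self, separable_vectors):
        vectors, labels = separable_vectors
        folds = _folds(labels, k=3)
        space = default_search_space(("lightgbm",), n_trials=4, seed=2)
        result = optimize_algorithm(vectors, labels, folds, "lightgbm", space)
        for trial in result.trace:
            for name, value in trial["params"].items():
                assert space.spaces["lightgbm"][name].contains(value)

    def test_single_fold_rejected(self, separable_vectors):
        vectors, labels = separable_vectors
        space = default_search_space(("knn",), n_trials=1)
        with pytest.raises(TrainingError, match="folds"):
            optimize_algorithm(vectors, labels, {0: set(labels)}, "knn", space)

    def test_degenerate_fold_named_in_error(self):
        vectors = {f"p{i}": np.ones(3) * i for i in range(6)}
        labels = {f"p{i}": int(i == 0) for i in range(6)}
        folds = {0: {"p0", "p1"}, 1: {"p2", "p3"}, 2: {"p4", "p5"}}
        space = default_search_space(("knn",), n_trials=1)
        with pytest.raises(TrainingError, match="single class"):
            optimize_algorithm(vectors, labels, folds, "knn", space)


class TestEnsemble:
    @pytest.mark.parametrize("algos,k,expected", [
        (("knn",), 5, 5),
        (("knn", "rfc"), 5, 10),
        (("knn", "rfc", "lightgbm"), 2, 6),
    ])
    def test_member_count_is_algorithms_times_folds(
        self, separable_vectors, algos, k, expected
    ):
        vectors, labels = separable_vectors
        folds = _folds(labels, k=k)
        space = default_search_space(algos, n_trials=1, seed=0)
        configs = {
            a: optimize_algorithm(vectors, labels, folds, a, space).best_params
            for a in algos
        }
        ens = fit_ensemble(vectors, labels, folds, configs)
        assert len(ens.members) == expected

    def test_prediction_is_convex_combination_of_members(self, fitted_ensemble):
        ens, vectors, _ = fitted_ensemble
        ids, member_scores = ens.member_scores(vectors)
        preds = ens.predict(vectors)
        for row, pid in zip(member_scores, ids):
            assert row.min() - 1e-12 <= preds[pid] <= row.max() + 1e-12
            assert preds[pid] == pytest.approx(row.mean())

    def test_prediction_invariant_to_member_order(self, fitted_ensemble):
        ens, vectors, _ = fitted_ensemble
        before = ens.predict(vectors)
        ens.members = list(reversed(ens.members))
        after = ens.predict(vectors)
        assert all(before[i] == pytest.approx(after[i]) for i in before)

    def test_dimension_mismatch_names_expected_width(self, fitted_ensemble):
        ens, _, _ = fitted_ensemble
        with pytest.raises(TrainingError, match="e=8"):
            ens.predict({"q": np.zeros(5)})

    def test_uncertainty_is_member_score_dispersion(self, fitted_ensemble):
        ens, vectors, _ = fitted_ensemble
        ids, member_scores = ens.member_scores(vectors)
        out = ens.predict_with_uncertainty(vectors)
        for row, pid in zip(member_scores, ids):
            assert out[pid][1] == pytest.approx(row.std())


class TestBundle:
    def test_round_trip_predictions_bit_identical(self, fitted_ensemble, tmp_path):
        ens, vectors, _ = fitted_ensemble
        probe = {k: vectors[k] for k in list(vectors)[:10]}
        before = ens.predict(probe)
        save_model(ens, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        after = loaded.predict(probe)
        assert all(before[i] == after[i] for i in before)

    def test_missing_member_file_rejected(self, fitted_ensemble, tmp_path):
        ens, _, _ = fitted_ensemble
        bundle = save_model(ens, tmp_path / "bundle")
        victim = next((bundle / "members").iterdir())
        victim.unlink()
        with pytest.raises(TrainingError, match="missing member"):
            load_model(bundle)

    def test_version_mismatch_rejected(self, fitted_ensemble, tmp_path):
        ens, _, _ = fitted_ensemble
        bundle = save_model(ens, tmp_path / "bundle")
        manifest = json.loads((bundle / "manifest.json").read_text())
        manifest["format_version"] = 99
        (bundle / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(TrainingError, match="version"):
            load_model(bundle)

    def test_manifest_lists_every_member(self, fitted_ensemble, tmp_path):
        ens, _, _ = fitted_ensemble
        bundle = save_model(ens, tmp_path / "bundle")
        manifest = json.loads((bundle / "manifest.json").read_text())
        assert len(manifest["members"]) == len(ens.members)
        assert manifest["train_ids"] == ens.train_ids
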