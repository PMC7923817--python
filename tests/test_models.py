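"""Labelling, splitting, the four classifiers, and cross-validation."""

import warnings

import numpy as np
import pytest

import hrvdoa as h
from hrvdoa.models import CLASS_CODES, MLPNetwork, decode_scores
from conftest import separable_clusters, short_sim_config

ALL_KINDS = ["lr", "svm", "dt", "dnn"]


def _random_dataset(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return h.Dataset(
        features=rng.normal(size=(n, 4)),
        labels=rng.choice(h.STATES, size=n),
        eacl=rng.uniform(0, 100, n),
        case_ids=rng.choice(["a", "b", "c"], size=n),
    )


class TestLabels:
    def test_states_from_timeline(self):
        cfg = h.SimConfig(
            n_cases=1,
            phase_mean_s={"I": 600.0, "II": 3600.0, "III": 900.0},
            phase_sd_frac=0.0,
        )
        tl = h.simulate_timeline(cfg, 0)
        labels = h.derive_labels(tl, [10.0, 599.9, 600.0, 4199.9, 4200.0, 5100.0])
        assert list(labels) == ["I", "I", "II", "II", "III", "III"]

    def test_centre_outside_timeline_rejected(self):
        tl = h.simulate_timeline(short_sim_config(), 0)
        with pytest.raises(h.DataError):
            h.derive_labels(tl, [tl.end_s + 1.0])

    def test_label_run_lengths_match_phase_durations(self):
        cfg = h.SimConfig(
            n_cases=1,
            phase_mean_s={"I": 600.0, "II": 3600.0, "III": 900.0},
            phase_sd_frac=0.0,
        )
        tl = h.simulate_timeline(cfg, 0)
        stride = 4.0
        centres = np.arange(stride / 2, tl.end_s, stride)
        labels = h.derive_labels(tl, centres)
        for state, duration in (("I", 600.0), ("II", 3600.0)):
            run = int(np.sum(labels == state))
            assert abs(run - duration / stride) <= 1


class TestSplit:
    def test_paper_scale_arithmetic(self):
        data = _random_dataset(n=46000, seed=1)
        train, test = h.split_dataset(data, h.SplitPlan(train_frac=0.8, seed=0))
        assert len(train) == 36800
        assert len(test) == 9200

    def test_tiny_split(self):
        data = _random_dataset(n=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 2-record test part may miss a state
            train, test = h.split_dataset(data, h.SplitPlan(train_frac=0.8, stratify_by="none"))
        assert len(train) == 8 and len(test) == 2

    def test_split_deterministic(self):
        data = _random_dataset(n=500)
        a = h.split_dataset(data, h.SplitPlan(seed=7))
        b = h.split_dataset(data, h.SplitPlan(seed=7))
        np.testing.assert_array_equal(a[0].features, b[0].features)
        np.testing.assert_array_equal(a[1].features, b[1].features)

    def test_partitions_disjoint_and_exhaustive(self):
        data = _random_dataset(n=500)
        train, test = h.split_dataset(data, h.SplitPlan())
        assert len(train) + len(test) == len(data)

    def test_case_grouped_split_keeps_cases_whole(self):
        data = _random_dataset(n=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train, test = h.split_dataset(data, h.SplitPlan(grouping="case"))
        assert set(np.unique(train.case_ids)).isdisjoint(np.unique(test.case_ids))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(h.ConfigurationError):
            h.SplitPlan(train_frac=1.2)


class TestTrain:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_separable_clusters_learned(self, kind):
        data = separable_clusters()
        model = h.train(h.ModelSpec(kind=kind, seed=0), data)
        pred, _ = h.predict(model, data.features)
        assert np.mean(pred == data.labels) >= 0.99

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_training_is_deterministic(self, kind):
        data = separable_clusters(n_per=60)
        a = h.train(h.ModelSpec(kind=kind, seed=3), data)
        b = h.train(h.ModelSpec(kind=kind, seed=3), data)
        pa, _ = h.predict(a, data.features)
        pb, _ = h.predict(b, data.features)
        np.testing.assert_array_equal(pa, pb)

    def test_missing_state_rejected(self):
        data = separable_clusters(n_per=50)
        keep = data.labels != "III"
        with pytest.raises(h.DataError):
            h.train(h.ModelSpec(kind="lr"), data.subset(keep))

    def test_constant_feature_column_rejected(self):
        data = separable_clusters(n_per=50)
        feats = data.features.copy()
        feats[:, 2] = 1.0
        bad = h.Dataset(feats, data.labels, data.eacl, data.case_ids)
        with pytest.raises(h.DataError):
            h.train(h.ModelSpec(kind="dnn"), bad)

    def test_dnn_loss_decreases(self):
        data = separable_clusters(n_per=100)
        model = h.train(h.ModelSpec(kind="dnn", seed=0), data)
        loss = model.estimator.loss_history
        assert loss[-1] < loss[0]

    def test_eacl_regression_head(self):
        data = separable_clusters(n_per=100)
        model = h.train(h.ModelSpec(kind="dnn", seed=0, target="eacl"), data)
        pred, raw = h.predict(model, data.features)
        assert raw is not None
        assert set(pred) <= set(h.STATES)


class TestDNNArchitecture:
    def test_layer_widths_and_parameter_count(self):
        net = MLPNetwork()
        assert net.layers == (4, 10, 17, 1)
        expected = sum(a * b + b for a, b in zip(net.layers[:-1], net.layers[1:]))
        assert net.n_parameters == expected

    def test_scalar_output_decoding(self):
        raw = np.array([0.49, 0.0, 1.2, 0.25, 0.75])
        decoded = decode_scores(raw, CLASS_CODES)
        # 0.25 and 0.75 are equidistant ties -> lower state wins
        assert list(decoded) == ["II", "I", "III", "I", "II"]

    def test_predict_requires_four_features(self):
        data = separable_clusters(n_per=30)
        model = h.train(h.ModelSpec(kind="dnn"), data)
        with pytest.raises(h.DataError):
            h.predict(model, np.zeros((5, 3)))


class TestCrossValidate:
    def test_separable_clusters_all_models(self):
        data = separable_clusters(n_per=100)
        specs = [h.ModelSpec(kind=k, seed=0) for k in ALL_KINDS]
        reports = h.cross_validate(data, specs, k=5, seed=0)
        assert len(reports) == 5
        for kind in ALL_KINDS:
            mean_acc = np.mean([fold[kind].accuracy for fold in reports])
            assert mean_acc >= 0.99

    def test_folds_partition_data(self):
        from sklearn.model_selection import StratifiedKFold

        data = separable_clusters(n_per=40)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        seen = np.concatenate([te for _, te in skf.split(data.features, data.labels)])
        assert sorted(seen) == list(range(len(data)))

    def test_k_larger_than_smallest_class_rejected(self):
        data = separable_clusters(n_per=3)
        with pytest.raises(h.ConfigurationError):
            h.cross_validate(data, [h.ModelSpec(kind="dt")], k=10)

    def test_label_permutation_collapses_accuracy(self):
        data = separable_clusters(n_per=200)
        rng = np.random.default_rng(42)
        shuffled = h.Dataset(
            data.features, rng.permutation(data.labels), data.eacl, data.case_ids
        )
        specs = [h.ModelSpec(kind=k, seed=0) for k in ALL_KINDS]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collapsed models may drop a state
            reports = h.cross_validate(shuffled, specs, k=5, seed=0)
        for kind in ALL_KINDS:
            mean_acc = np.mean([fold[kind].accuracy for fold in reports])
            assert abs(mean_acc - 1 / 3) <= 0.05


def test_model_roundtrip_serialization(tmp_path):
    data = separable_clusters(n_per=50)
    for kind in ALL_KINDS:
        model = h.train(h.ModelSpec(kind=kind, seed=0), data)
        path = tmp_path / f"model_{kind}.json"
        h.save_model(model, path)
        loaded = h.load_model(path)
        pa, _ = h.predict(model, data.features)
        pb, _ = h.predict(loaded, data.features)
        np.testing.assert_array_equal(pa, pb)


def test_dnn_crosscheck_against_reference_mlp():
    """An independently fitted reference MLP (same architecture, scikit-learn)
    reaches comparable accuracy on a noisy 3-cluster problem."""
    from sklearn.neural_network import MLPRegressor

    data = separable_clusters(n_per=150, sep=2.0, seed=5)
    model = h.train(h.ModelSpec(kind="dnn", seed=0), data)
    ours, _ = h.predict(model, data.features)
    acc_ours = np.mean(ours == data.labels)

    X = (data.features - data.features.mean(0)) / data.features.std(0)
    y = np.array([CLASS_CODES[s] for s in data.labels])
    ref = MLPRegressor(hidden_layer_sizes=(10, 17), activation="relu",
                       solver="adam", max_iter=2000, random_state=0).fit(X, y)
    ref_pred = decode_scores(ref.predict(X), CLASS_CODES)
    acc_ref = np.mean(ref_pred == data.labels)
    assert abs(acc_ours - acc_ref) < 0.05
    assert acc_ours > 0.9
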