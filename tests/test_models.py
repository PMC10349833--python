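import numpy as np
import pytest

from dermasp import SplitSpec, build_classifier, build_network, generate_feature_table, predict, split_dataset, train_model, zscore_fit_transform
from dermasp.models import MODEL_NAMES, build_network_model, build_spec


def _prepared(n_per_class, separation, seed):
    df = generate_feature_table(n_per_class, separation, seed=seed)
    tr_raw, te_raw = split_dataset(df, SplitSpec(0.7, seed=seed))
    tr, te, _ = zscore_fit_transform(tr_raw, te_raw)
    return tr, te


class TestBuildSpecs:
    def test_rf_defaults(self):
        spec = build_classifier("RF")
        assert spec.hyperparameters["n_estimators"] == 100
        assert spec.hyperparameters["criterion"] == "entropy"

    def test_knn_defaults(self):
        hp = build_classifier("KNN").hyperparameters
        assert hp["n_neighbors"] == 1 and hp["metric"] == "euclidean"
        assert hp["algorithm"] == "kd_tree" and hp["leaf_size"] == 20

    def test_svm_ad_dt_gnb_defaults(self):
        assert build_classifier("SVM").hyperparameters["kernel"] == "linear"
        ad = build_classifier("AD").hyperparameters
        assert ad["n_estimators"] == 100 and ad["random_state"] == 40
        dt = build_classifier("DT").hyperparameters
        assert dt["criterion"] == "entropy" and dt["max_depth"] == 100
        assert build_classifier("GNB").hyperparameters["var_smoothing"] == 1e-9

    def test_override(self):
        assert build_classifier("RF", {"n_estimators": 10}).hyperparameters["n_estimators"] == 10

    def test_unknown_names_rejected_with_listing(self):
        with pytest.raises(ValueError, match="RF"):
            build_classifier("XGB")
        with pytest.raises(ValueError, match="PRNN"):
            build_network("LSTM")

    def test_fnn_architecture(self):
        assert build_network("FNN").hyperparameters["hidden_units"] == (10, 8, 6)

    def test_cnn_first_conv(self):
        hp = build_network("CNN1D").hyperparameters
        assert hp["conv_filters"][0] == 64 and hp["kernel_sizes"][0] == 2

    def test_cnn_parameter_count_closed_form(self):
        """Layer-shape arithmetic: conv 192 + conv 2080 + dense 5152 + dense 33."""
        net = build_network_model(build_spec("CNN1D"))
        expected = (2 * 1 + 1) * 64 + (1 * 64 + 1) * 32 + (5 * 32) * 32 + 32 + 32 + 1
        assert net.count_params() == expected == 7457

    def test_prnn_fnn_parameter_counts(self):
        assert build_network_model(build_spec("PRNN")).count_params() == 7 * 10 + 11
        assert build_network_model(build_spec("FNN")).count_params() == 70 + 88 + 54 + 7


class TestTrainPredict:
    def test_knn_memorizes_training_set(self):
        tr, _ = _prepared(100, 2.0, seed=0)
        model = train_model(build_spec("KNN"), tr, cv_folds=None)
        assert (predict(model, tr) == tr["class"].to_numpy()).all()

    def test_unpruned_tree_memorizes(self):
        tr, _ = _prepared(100, 2.0, seed=1)
        model = train_model(build_spec("DT", seed=1), tr, cv_folds=None)
        assert (predict(model, tr) == tr["class"].to_numpy()).all()

    def test_rf_cv_accuracy_on_separable_data(self):
        """Monte-Carlo over 5 seeds at Mahalanobis separation 4."""
        accs = []
        for seed in range(5):
            tr, _ = _prepared(500, 4.0, seed=seed)
            model = train_model(build_spec("RF", seed=seed), tr, cv_folds=5)
            accs.append(model.cv_mean_accuracy)
        assert np.mean(accs) >= 0.95

    def test_no_signal_null_accuracy(self):
        """At separation 0 every model hovers around chance."""
        per_model = {name: [] for name in MODEL_NAMES}
        for seed in range(3):
            tr, te = _prepared(250, 0.0, seed=seed)
            for name in MODEL_NAMES:
                model = train_model(build_spec(name, seed=seed), tr, cv_folds=None)
                per_model[name].append((predict(model, te) == te["class"].to_numpy()).mean())
        for name, accs in per_model.items():
            assert 0.4 <= np.mean(accs) <= 0.6, name

    def test_all_models_beat_majority_baseline_at_separation_2(self):
        per_model = {name: [] for name in MODEL_NAMES}
        for seed in range(5):
            tr, te = _prepared(250, 2.0, seed=seed)
            baseline = max(te["class"].mean(), 1 - te["class"].mean())
            for name in MODEL_NAMES:
                model = train_model(build_spec(name, seed=seed), tr, cv_folds=None)
                acc = (predict(model, te) == te["class"].to_numpy()).mean()
                per_model[name].append(acc - baseline)
        for name, margins in per_model.items():
            assert np.mean(margins) > 0, name

    def test_single_class_train_rejected(self):
        tr, _ = _prepared(50, 1.0, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_model(build_spec("RF"), tr[tr["class"] == 0])

    def test_empty_prediction(self):
        tr, te = _prepared(50, 1.0, seed=0)
        model = train_model(build_spec("GNB"), tr, cv_folds=None)
        assert len(predict(model, te.iloc[:0])) == 0

    def test_seeded_determinism(self):
        tr, te = _prepared(150, 1.0, seed=4)
        for name in ("RF", "AD", "DT", "FNN"):
            a = train_model(build_spec(name, seed=5), tr, cv_folds=None)
            b = train_model(build_spec(name, seed=5), tr, cv_folds=None)
            assert np.array_equal(predict(a, te), predict(b, te)), name

    def test_network_threshold_at_half(self):
        """Sigmoid outputs strictly above 0.5 map to class 1, below to 0."""
        from dermasp import nn

        net = nn.Sequential([nn.Dense(1, "sigmoid")], (6,), seed=0)
        net.layers[0].w[:] = 0.0
        net.layers[0].b[:] = np.log(0.51 / 0.49)  # sigmoid -> 0.51
        x = np.zeros((3, 6))
        assert np.allclose(net.predict_proba(x), 0.51)
        assert ((net.predict_proba(x) > 0.5).astype(int) == 1).all()
        net.layers[0].b[:] = np.log(0.49 / 0.51)
        assert ((net.predict_proba(x) > 0.5).astype(int) == 0).all()
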