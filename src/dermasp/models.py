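"""The nine superpixel classifiers and their training protocol.

Six classical learners (random forest, linear SVM, AdaBoost, 1-NN, decision
tree, Gaussian naive Bayes) are scikit-learn estimators carrying the study's
hyperparameters; three neural networks (pattern-recognition network, feed
forward network, 1-D CNN) are built on the in-package numpy layer framework
with the documented architectures.  All nine consume the six z-scored
geometric features per superpixel and output labels in {0: nevus,
1: melanoma}; networks threshold their sigmoid output at 0.5.

Training fits on the full training partition and additionally records the
mean five-fold cross-validation accuracy as overfitting diagnostics.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import nn
from .dataset import FEATURE_COLUMNS, kfold_indices

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "ML_NAMES",
    "NETWORK_NAMES",
    "MODEL_NAMES",
    "build_classifier",
    "build_network",
    "build_spec",
    "train_model",
    "predict",
]

ML_NAMES = ("RF", "SVM", "AD", "KNN", "DT", "GNB")
NETWORK_NAMES = ("PRNN", "FNN", "CNN1D")
MODEL_NAMES = ML_NAMES + NETWORK_NAMES

_ML_DEFAULTS: dict[str, dict] = {
    "RF": {"n_estimators": 100, "criterion": "entropy"},
    "SVM": {
        "kernel": "linear",
        "degree": 2,
        "gamma": "scale",
        "cache_size": 100,
        "decision_function_shape": "ovo",
    },
    "AD": {"n_estimators": 100, "algorithm": "SAMME", "random_state": 40},
    "KNN": {
        "n_neighbors": 1,
        "weights": "uniform",
        "algorithm": "kd_tree",
        "leaf_size": 20,
        "p": 2,
        "metric": "euclidean",
    },
    "DT": {
        "criterion": "entropy",
        "splitter": "best",
        "max_depth": 100,
        "ccp_alpha": 0.0,
    },
    "GNB": {"priors": None, "var_smoothing": 1e-09},
}

_NETWORK_DEFAULTS: dict[str, dict] = {
    # Scaled-conjugate-gradient training is approximated by a full-batch
    # gradient optimizer on the same 10-unit architecture and loss.
    "PRNN": {
        "hidden_units": 10,
        "epochs": 100,
        "learning_rate": 0.01,
        "optimizer": "gd",
        "batch_size": None,
    },
    "FNN": {
        "hidden_units": (10, 8, 6),
        "activation": "tanh",
        "epochs": 100,
        "learning_rate": 0.001,
        "optimizer": "adam",
        "batch_size": 32,
    },
    "CNN1D": {
        "conv_filters": (64, 32),
        "kernel_sizes": (2, 1),
        "dropout": 0.2,
        "pool_size": 1,
        "dense_units": 32,
        "epochs": 100,
        "learning_rate": 0.001,
        "optimizer": "adam",
        "batch_size": 32,
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hyperparameters: dict
    seed: int = 0


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    fitted: object  # sklearn estimator or nn.Sequential
    cv_mean_accuracy: float | None = None
    epochs_run: int = 0


def build_classifier(name: str, overrides: dict | None = None, seed: int = 0) -> ClassifierSpec:
    """Spec for one of the six classical learners with the study defaults."""
    if name not in ML_NAMES:
        raise ValueError(f"unknown classifier {name!r}; valid names: {list(ML_NAMES)}")
    params = dict(_ML_DEFAULTS[name])
    params.update(overrides or {})
    return ClassifierSpec(name=name, hyperparameters=params, seed=seed)


def build_network(name: str, overrides: dict | None = None, seed: int = 0) -> ClassifierSpec:
    """Spec for one of the three neural networks with the documented defaults."""
    if name not in NETWORK_NAMES:
        raise ValueError(f"unknown network {name!r}; valid names: {list(NETWORK_NAMES)}")
    params = dict(_NETWORK_DEFAULTS[name])
    params.update(overrides or {})
    return ClassifierSpec(name=name, hyperparameters=params, seed=seed)


def build_spec(name: str, overrides: dict | None = None, seed: int = 0) -> ClassifierSpec:
    if name in ML_NAMES:
        return build_classifier(name, overrides, seed)
    if name in NETWORK_NAMES:
        return build_network(name, overrides, seed)
    raise ValueError(f"unknown model {name!r}; valid names: {list(MODEL_NAMES)}")


def _sklearn_estimator(spec: ClassifierSpec):
    params = dict(spec.hyperparameters)
    if spec.name == "RF":
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.name == "SVM":
        return SVC(random_state=spec.seed, **params)
    if spec.name == "AD":
        # Newer scikit-learn removed the `algorithm` parameter; SAMME is then
        # the only (and default) boosting variant, so dropping it is lossless.
        if "algorithm" not in inspect.signature(AdaBoostClassifier).parameters:
            params.pop("algorithm", None)
        return AdaBoostClassifier(**params)
    if spec.name == "KNN":
        return KNeighborsClassifier(**params)
    if spec.name == "DT":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    if spec.name == "GNB":
        return GaussianNB(**params)
    raise ValueError(spec.name)


def build_network_model(spec: ClassifierSpec, n_features: int = 6) -> nn.Sequential:
    """Instantiate the (untrained) numpy network described by a spec."""
    hp = spec.hyperparameters
    if spec.name == "PRNN":
        layers = [nn.Dense(hp["hidden_units"], "tanh"), nn.Dense(1, "sigmoid")]
        input_shape: tuple = (n_features,)
    elif spec.name == "FNN":
        layers = [nn.Dense(u, hp["activation"]) for u in hp["hidden_units"]]
        layers.append(nn.Dense(1, "sigmoid"))
        input_shape = (n_features,)
    elif spec.name == "CNN1D":
        f1, f2 = hp["conv_filters"]
        k1, k2 = hp["kernel_sizes"]
        layers = [
            nn.Conv1D(f1, k1, "relu"),
            nn.Dropout(hp["dropout"]),
            nn.Conv1D(f2, k2, "relu"),
            nn.MaxPool1D(hp["pool_size"]),
            nn.Flatten(),
            nn.Dense(hp["dense_units"], "relu"),
            nn.Dense(1, "sigmoid"),
        ]
        input_shape = (n_features, 1)
    else:
        raise ValueError(spec.name)
    return nn.Sequential(
        layers,
        input_shape,
        learning_rate=hp["learning_rate"],
        optimizer=hp["optimizer"],
        seed=spec.seed,
    )


def _xy(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = data[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    y = data["class"].to_numpy(dtype=np.int64)
    return x, y


def _fit_once(spec: ClassifierSpec, x: np.ndarray, y: np.ndarray, seed: int):
    if spec.name in ML_NAMES:
        est = _sklearn_estimator(
            ClassifierSpec(spec.name, spec.hyperparameters, seed=seed)
        )
        return est.fit(x, y)
    net = build_network_model(ClassifierSpec(spec.name, spec.hyperparameters, seed))
    hp = spec.hyperparameters
    return net.fit(x, y, epochs=hp["epochs"], batch_size=hp["batch_size"])


def _predict_fitted(fitted, x: np.ndarray) -> np.ndarray:
    if isinstance(fitted, nn.Sequential):
        return (fitted.predict_proba(x) > 0.5).astype(np.int64)
    return fitted.predict(x).astype(np.int64)


def train_model(
    spec: ClassifierSpec, train: pd.DataFrame, cv_folds: int | None = 5
) -> TrainedModel:
    """Fit on the full training partition, recording k-fold CV mean accuracy.

    The training features are expected to be normalized already.  Per-fold
    models are refitted from scratch with fold-derived seeds.
    """
    x, y = _xy(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    cv_acc = None
    if cv_folds:
        accs = []
        for i, (tr, val) in enumerate(kfold_indices(len(x), cv_folds, spec.seed)):
            fitted = _fit_once(spec, x[tr], y[tr], seed=spec.seed + i + 1)
            accs.append(float((_predict_fitted(fitted, x[val]) == y[val]).mean()))
        cv_acc = float(np.mean(accs))
    fitted = _fit_once(spec, x, y, seed=spec.seed)
    epochs = spec.hyperparameters.get("epochs", 0) if spec.name in NETWORK_NAMES else 0
    return TrainedModel(spec=spec, fitted=fitted, cv_mean_accuracy=cv_acc, epochs_run=epochs)


def predict(model: TrainedModel, data: pd.DataFrame) -> np.ndarray:
    """Predicted labels in {0, 1}, one per record; empty input -> empty output."""
    if len(data) == 0:
        return np.zeros(0, dtype=np.int64)
    x = data[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    if x.shape[1] != 6:
        raise ValueError(f"expected 6 features, got {x.shape[1]}")
    return _predict_fitted(model.fitted, x)
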