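"""Classifiers: the SIELU/GELU neural network plus SVM and RF baselines.

The network mirrors the published architecture: a 150-unit input layer with
He-normal initialization and a selectable activation (sielu, gelu, relu,
tanh, sigmoid), a 50-unit hidden layer with 0.02 dropout, and a 1-unit
sigmoid output trained with Adam on mean-squared error for 500 epochs.
Two input modes are provided:

``dense``
    46 -> 150 -> 50 -> 1 feed-forward reference (14,701 parameters).
``recurrent``
    the 46 features enter a one-step gated recurrent (LSTM-style) layer of
    150 units — each sample is a length-1 sequence with 46 channels — then
    the same 50-unit hidden and sigmoid output stack.  With a zero initial
    state the forget gate is inert and omitted; the candidate gate uses the
    configured activation.

Everything is pure numpy with manual backpropagation, so training is
bit-reproducible under a fixed seed and single-threaded execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array

from .activations import get_activation, sigmoid
from .dataprep import stratified_kfold, stratified_split, SplitSpec
from .evaluation import MetricsReport, confusion, metrics

__all__ = [
    "ModelConfig",
    "BaselineConfig",
    "TrainingDivergedError",
    "build_network",
    "train",
    "predict_proba",
    "predict_label",
    "ActivationNetClassifier",
    "make_svm_baseline",
    "make_rf_baseline",
    "train_svm_baseline",
    "train_rf_baseline",
    "cross_validate",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters of the network."""

    input_units: int = 150
    hidden_units: int = 50
    dropout_rate: float = 0.02
    activation: str = "sielu"
    loss: str = "mse"  # "mse" (published default) or "bce"
    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    input_mode: str = "recurrent"  # "recurrent" (length-1 LSTM) or "dense"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_units <= 0 or self.hidden_units <= 0:
            raise ValueError("unit counts must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.input_mode not in ("recurrent", "dense"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        get_activation(self.activation)  # fail fast on unknown names


@dataclass(frozen=True)
class BaselineConfig:
    """Published baseline hyperparameters: polynomial-kernel SVM and RF."""

    svm_gamma: float = 0.01
    rf_min_weight_fraction_leaf: float = 0.1
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.svm_gamma <= 0 or self.rf_min_weight_fraction_leaf <= 0:
            raise ValueError("baseline parameters must be positive")


def _he_normal(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class _Network:
    """Numpy network with manual backprop; see module docstring for shapes."""

    def __init__(self, config: ModelConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        self.act, self.act_grad = get_activation(config.activation)
        rng = np.random.default_rng(config.seed)
        c = config
        self.weights: dict[str, np.ndarray] = {}
        if c.input_mode == "dense":
            self._add(rng, "W1", n_features, c.input_units)
        else:  # recurrent: input, candidate and output gates
            for gate in ("i", "g", "o"):
                self._add(rng, f"W{gate}", n_features, c.input_units)
        self._add(rng, "W2", c.input_units, c.hidden_units)
        self._add(rng, "W3", c.hidden_units, 1)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([c.seed, 1])
        )

    def _add(self, rng, name: str, fan_in: int, fan_out: int) -> None:
        self.weights[name] = _he_normal(rng, fan_in, fan_out)
        self.weights["b" + name[1:]] = np.zeros(fan_out)

    def parameter_count(self) -> int:
        return sum(w.size for w in self.weights.values())

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray, train_mode: bool = False) -> np.ndarray:
        W, c = self.weights, self.config
        cache: dict[str, np.ndarray] = {"X": X}
        if c.input_mode == "dense":
            z1 = X @ W["W1"] + W["b1"]
            a1 = np.asarray(self.act(z1))
            cache["z1"] = z1
        else:
            zi = X @ W["Wi"] + W["bi"]
            zg = X @ W["Wg"] + W["bg"]
            zo = X @ W["Wo"] + W["bo"]
            i = np.asarray(sigmoid(zi))
            g = np.asarray(self.act(zg))
            o = np.asarray(sigmoid(zo))
            cell = i * g
            tc = np.tanh(cell)
            a1 = o * tc
            cache.update(zi=zi, zg=zg, zo=zo, i=i, g=g, o=o, cell=cell, tc=tc)
        z2 = a1 @ W["W2"] + W["b2"]
        a2 = np.asarray(self.act(z2))
        if train_mode and c.dropout_rate > 0:
            mask = (
                self._dropout_rng.random(a2.shape) >= c.dropout_rate
            ).astype(float) / (1.0 - c.dropout_rate)
            a2 = a2 * mask
            cache["drop_mask"] = mask
        z3 = a2 @ W["W3"] + W["b3"]
        p = np.asarray(sigmoid(z3))
        cache.update(a1=a1, z2=z2, a2=a2, z3=z3, p=p)
        self._cache = cache
        return p[:, 0]

    # -- backward ---------------------------------------------------------
    def backward(self, y: np.ndarray) -> dict[str, np.ndarray]:
        W, c, cache = self.weights, self.config, self._cache
        X, p = cache["X"], cache["p"]
        n = len(y)
        yv = y.reshape(-1, 1).astype(float)
        if c.loss == "mse":
            # d/dz3 of mean (p - y)^2 with p = sigmoid(z3)
            dz3 = 2.0 * (p - yv) * p * (1.0 - p) / n
        else:  # bce
            dz3 = (p - yv) / n
        grads: dict[str, np.ndarray] = {}
        grads["W3"] = cache["a2"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        da2 = dz3 @ W["W3"].T
        if "drop_mask" in cache:
            da2 = da2 * cache["drop_mask"]
        dz2 = da2 * np.asarray(self.act_grad(cache["z2"]))
        grads["W2"] = cache["a1"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ W["W2"].T
        if c.input_mode == "dense":
            dz1 = da1 * np.asarray(self.act_grad(cache["z1"]))
            grads["W1"] = X.T @ dz1
            grads["b1"] = dz1.sum(axis=0)
        else:
            i, g, o, tc = cache["i"], cache["g"], cache["o"], cache["tc"]
            do = da1 * tc
            dcell = da1 * o * (1.0 - tc**2)
            di = dcell * g
            dg = dcell * i
            dzi = di * i * (1.0 - i)
            dzg = dg * np.asarray(self.act_grad(cache["zg"]))
            dzo = do * o * (1.0 - o)
            for gate, dz in (("i", dzi), ("g", dzg), ("o", dzo)):
                grads[f"W{gate}"] = X.T @ dz
                grads[f"b{gate}"] = dz.sum(axis=0)
        return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], config: ModelConfig):
        self.c = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        c = self.c
        self.t += 1
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g**2
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            params[k] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


def _loss_value(p: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "mse":
        return float(np.mean((p - y) ** 2))
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def build_network(config: ModelConfig, n_features: int = 46) -> _Network:
    """Instantiate an untrained network with He-normal seeded weights."""
    return _Network(config, n_features)


def train(
    net: _Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict[str, list[float]]:
    """Run exactly ``config.epochs`` epochs of minibatch Adam; return history.

    History holds one (train_acc, val_acc, loss) triple per epoch, measured
    in evaluation mode (dropout off) after each epoch.  A non-finite loss
    aborts with :class:`TrainingDivergedError`.
    """
    c = net.config
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if not np.all(np.isfinite(X_train)):
        raise ValueError("non-finite values in X_train")
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, 2]))
    opt = _Adam(net.weights, c)
    history: dict[str, list[float]] = {"train_acc": [], "val_acc": [], "loss": []}
    n = len(X_train)
    for _epoch in range(c.epochs):
        order = rng.permutation(n)
        try:
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                net.forward(X_train[idx], train_mode=True)
                grads = net.backward(y_train[idx])
                opt.step(net.weights, grads)
            p_train = net.forward(X_train, train_mode=False)
        except ValueError as exc:
            # inputs were validated above, so a non-finite pre-activation here
            # means the optimization itself blew up
            raise TrainingDivergedError(
                f"non-finite values during epoch {_epoch + 1}: {exc}"
            ) from exc
        loss = _loss_value(p_train, y_train, c.loss)
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {_epoch + 1}: {loss}"
            )
        history["loss"].append(loss)
        history["train_acc"].append(float(np.mean((p_train >= 0.5) == y_train)))
        if X_val is not None and len(X_val):
            p_val = net.forward(np.asarray(X_val, dtype=float), train_mode=False)
            yv = np.asarray(y_val, dtype=float).ravel()
            history["val_acc"].append(float(np.mean((p_val >= 0.5) == yv)))
        else:
            history["val_acc"].append(float("nan"))
    return history


def predict_proba(net: _Network, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities in [0, 1]."""
    return net.forward(np.asarray(X, dtype=float), train_mode=False)


def predict_label(net: _Network, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: probability >= threshold."""
    return (predict_proba(net, X) >= threshold).astype(int)


class ActivationNetClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style estimator around the numpy network.

    Parameters mirror :class:`ModelConfig`; ``validation_fraction`` carves a
    stratified validation set out of the training data for the per-epoch
    history (pass explicit validation data to ``fit`` to override).
    ``expected_schema_hash`` rejects feature tables produced under a
    different :class:`~sielunet.features.FeatureSchema`.
    """

    def __init__(
        self,
        activation: str = "sielu",
        input_units: int = 150,
        hidden_units: int = 50,
        dropout_rate: float = 0.02,
        loss: str = "mse",
        epochs: int = 500,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        input_mode: str = "recurrent",
        validation_fraction: float = 0.2,
        expected_schema_hash: str | None = None,
        random_state: int = 0,
    ):
        self.activation = activation
        self.input_units = input_units
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.loss = loss
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.input_mode = input_mode
        self.validation_fraction = validation_fraction
        self.expected_schema_hash = expected_schema_hash
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            input_units=self.input_units,
            hidden_units=self.hidden_units,
            dropout_rate=self.dropout_rate,
            activation=self.activation,
            loss=self.loss,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            input_mode=self.input_mode,
            seed=self.random_state,
        )

    def _check_schema(self, schema_hash: str | None) -> None:
        expected = getattr(self, "schema_hash_", self.expected_schema_hash)
        if expected is not None and schema_hash is not None and schema_hash != expected:
            raise ValueError(
                f"feature schema hash {schema_hash!r} does not match the hash "
                f"this model was trained with ({expected!r})"
            )

    def fit(self, X, y, validation_data=None, schema_hash: str | None = None):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification requires exactly 2 classes")
        y01 = (y == self.classes_[1]).astype(float)
        self.schema_hash_ = (
            schema_hash if schema_hash is not None else self.expected_schema_hash
        )
        self._check_schema(schema_hash)
        if validation_data is not None:
            X_core, y_core = X, y01
            X_val, y_val = validation_data
            y_val = (np.asarray(y_val) == self.classes_[1]).astype(float)
        elif self.validation_fraction > 0:
            split = stratified_split(
                y01,
                SplitSpec(
                    train_fraction=1.0 - self.validation_fraction,
                    seed=self.random_state,
                ),
            )
            core, val = split["train"], split["test"]
            X_core, y_core = X[core], y01[core]
            X_val, y_val = X[val], y01[val]
        else:
            X_core, y_core, X_val, y_val = X, y01, None, None
        self.network_ = build_network(self._config(), n_features=X.shape[1])
        self.history_ = train(self.network_, X_core, y_core, X_val, y_val)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X, schema_hash: str | None = None):
        self._check_schema(schema_hash)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return predict_proba(self.network_, X)

    def predict_proba(self, X, schema_hash: str | None = None):
        p = self.decision_function(X, schema_hash)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, threshold: float = 0.5, schema_hash: str | None = None):
        p = self.decision_function(X, schema_hash)
        return self.classes_[(p >= threshold).astype(int)]

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Portable JSON container: config, schema hash, weights, history."""
        payload = {
            "params": self.get_params(),
            "schema_hash": getattr(self, "schema_hash_", None),
            "classes": np.asarray(self.classes_).tolist(),
            "n_features_in": self.n_features_in_,
            "weights": {k: v.tolist() for k, v in self.network_.weights.items()},
            "history": self.history_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ActivationNetClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        obj = cls(**payload["params"])
        obj.classes_ = np.asarray(payload["classes"])
        obj.n_features_in_ = payload["n_features_in"]
        obj.schema_hash_ = payload["schema_hash"]
        obj.history_ = payload["history"]
        obj.network_ = build_network(
            obj._config(), n_features=obj.n_features_in_
        )
        obj.network_.weights = {
            k: np.asarray(v) for k, v in payload["weights"].items()
        }
        return obj


def make_svm_baseline(config: BaselineConfig = BaselineConfig()) -> SVC:
    """Polynomial-kernel SVM with kernel coefficient 0.01."""
    return SVC(kernel="poly", gamma=config.svm_gamma, random_state=config.seed)


def make_rf_baseline(config: BaselineConfig = BaselineConfig()) -> RandomForestClassifier:
    """Random forest with minimum leaf weight fraction 0.1."""
    return RandomForestClassifier(
        min_weight_fraction_leaf=config.rf_min_weight_fraction_leaf,
        random_state=config.seed,
    )


def _fit_baseline(est, X, y):
    X, y = check_X_y(X, y)
    if np.unique(y).size < 2:
        raise ValueError("degenerate single-class input")
    return est.fit(X, y)


def train_svm_baseline(X, y, config: BaselineConfig = BaselineConfig()) -> SVC:
    return _fit_baseline(make_svm_baseline(config), X, y)


def train_rf_baseline(
    X, y, config: BaselineConfig = BaselineConfig()
) -> RandomForestClassifier:
    return _fit_baseline(make_rf_baseline(config), X, y)


def cross_validate(
    model_builder: Callable[[], BaseEstimator],
    X,
    y,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold evaluation; per-fold reports plus mean/sd summary."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in stratified_kfold(y, n_folds=n_folds, seed=seed):
        est = model_builder()
        est.fit(X[train_idx], y[train_idx])
        y_pred = est.predict(X[test_idx])
        reports.append(metrics(confusion(y[test_idx], y_pred)))
    fields = ("accuracy", "precision", "recall", "f1", "specificity", "mcc")
    summary = {
        name: {
            "mean": float(np.mean([getattr(r, name) for r in reports])),
            "sd": float(np.std([getattr(r, name) for r in reports])),
        }
        for name in fields
    }
    return {"folds": reports, "summary": summary}
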