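"""Tabular risk models on encoded PROMs.

Two interchangeable classifiers, as in the study design: a small
sequential multilayer perceptron, and a multivariable logistic regression
comparator fitted by unpenalised maximum likelihood on the same inputs.
Both output a per-response probability of the outcome of interest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import _engine as eng


def _validate_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(float).ravel()
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must be binary 0/1")
    if classes.size < 2:
        raise ValueError("y contains a single class; cannot fit a classifier")
    return y


class TabularRiskClassifier(BaseEstimator, ClassifierMixin):
    """MLP or logistic-regression risk model for encoded PROMs.

    Parameters
    ----------
    kind:
        ``"mlp"`` — sequential network with hidden widths ``hidden``,
        rectified activations and a sigmoid output, trained with Adam and
        plateau early stopping on the training loss;
        ``"logistic"`` — unpenalised maximum-likelihood logistic
        regression (the comparator model).
    hidden:
        Hidden layer widths for the MLP.
    max_epochs, batch_size, learning_rate, patience:
        MLP training schedule; training stops early when the epoch-level
        training loss has not improved for ``patience`` epochs.
    class_weight:
        ``"balanced"`` (inverse-prevalence sample weights for the MLP,
        stabilising training at rare event rates) or ``None``. The
        logistic comparator is always an unweighted maximum-likelihood
        fit so its coefficients estimate the usual odds ratios.
    random_state:
        Seed for weight initialisation and batch shuffling.
    """

    def __init__(
        self,
        kind: str = "mlp",
        hidden: tuple[int, ...] = (16, 8),
        max_epochs: int = 200,
        batch_size: int = 32,
        learning_rate: float = 0.01,
        patience: int = 10,
        class_weight: str | None = "balanced",
        random_state: int = 0,
    ):
        self.kind = kind
        self.hidden = hidden
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        y = _validate_binary(y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        if self.kind == "logistic":
            self._lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-12)
            self._lr.fit(X, y)
            self.coef_ = self._lr.coef_.copy()
            self.intercept_ = self._lr.intercept_.copy()
            self.training_meta_ = {"kind": "logistic", "n_iter": int(self._lr.n_iter_[0])}
        elif self.kind == "mlp":
            rng = np.random.default_rng(np.random.SeedSequence([int(self.random_state), 0x3A7]))
            layers: list[eng.Layer] = []
            widths = [X.shape[1], *self.hidden]
            for a, b in zip(widths[:-1], widths[1:]):
                layers += [eng.Dense(a, b, rng), eng.ReLU()]
            layers.append(eng.Dense(widths[-1], 1, rng))
            self._net = eng.Sequential(layers)
            weights = None
            if self.class_weight == "balanced":
                p = y.mean()
                weights = np.where(y == 1, 0.5 / p, 0.5 / (1 - p))
            steps_per_epoch = int(np.ceil(len(y) / self.batch_size))
            self.training_meta_ = eng.train_network(
                self._net,
                X,
                y,
                optimizer=eng.Adam(lr=self.learning_rate),
                epochs=self.max_epochs,
                batch_size=self.batch_size,
                rng=rng,
                sample_weight=weights,
                eval_every=steps_per_epoch,
                patience=self.patience,
            )
            self.training_meta_["kind"] = "mlp"
        else:
            raise ValueError(f"unknown kind: {self.kind!r} (expected 'mlp' or 'logistic')")
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features but model was fitted with {self.n_features_in_}"
            )
        if self.kind == "logistic":
            p = self._lr.predict_proba(X)[:, 1]
        else:
            p = eng.sigmoid(self._net.forward(X).ravel())
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        check_is_fitted(self, "classes_")
        path = Path(path)
        meta = {"params": self.get_params(), "n_features_in": int(self.n_features_in_)}
        if self.kind == "logistic":
            arrays = {"coef": self.coef_, "intercept": self.intercept_}
        else:
            arrays = {f"w{i}": w for i, w in enumerate(self._net.get_weights())}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TabularRiskClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()})
            model.classes_ = np.array([0, 1])
            model.n_features_in_ = meta["n_features_in"]
            if model.kind == "logistic":
                model._lr = LogisticRegression(C=np.inf)
                model._lr.classes_ = np.array([0.0, 1.0])
                model._lr.coef_ = data["coef"]
                model._lr.intercept_ = data["intercept"]
                model.coef_ = data["coef"]
                model.intercept_ = data["intercept"]
            else:
                rng = np.random.default_rng(0)
                layers: list[eng.Layer] = []
                widths = [model.n_features_in_, *model.hidden]
                for a, b in zip(widths[:-1], widths[1:]):
                    layers += [eng.Dense(a, b, rng), eng.ReLU()]
                layers.append(eng.Dense(widths[-1], 1, rng))
                model._net = eng.Sequential(layers)
                model._net.set_weights([data[f"w{i}"] for i in range(len(model._net.params()))])
        model.training_meta_ = {"kind": model.kind, "loaded": True}
        return model


def fit_tabular(X, y, kind: str = "mlp", seed: int = 0, **kwargs) -> TabularRiskClassifier:
    """Fit a tabular risk model of the given kind (thin estimator wrapper)."""
    return TabularRiskClassifier(kind=kind, random_state=seed, **kwargs).fit(X, y)


def predict_tabular(model: TabularRiskClassifier, X) -> np.ndarray:
    """Per-row outcome probabilities in [0, 1]."""
    return model.predict_proba(X)[:, 1]
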