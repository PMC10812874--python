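"""Learners for paired drug-response regression.

Three predictors share one contract (scikit-learn estimator API over the
concatenated (x_c || x_d) design matrix, squared-error objective, validation
-based early stopping where applicable):

* :class:`DrugMeanRegressor` — the rule-based benchmark: predict each drug's
  training-set mean ln(IC50), falling back to the global training mean for a
  drug never seen in training.  It ignores the omics features entirely, so
  beating it is the bar any omics-aware model must clear.
* :class:`GradientBoostedLearner` — gradient-boosted trees (XGBoost backend)
  with boosting halted by early stopping on a held-out validation set.
* :class:`NeuralNetworkLearner` — a dense feed-forward network on the
  concatenated inputs, trained epoch-by-epoch with validation-based early
  stopping and patience; weights are restored to the best epoch.

:func:`random_search` draws seeded hyperparameter assignments from a
:class:`HyperparameterSpace`, fits each, and keeps the model with minimal
validation MSE (ties break toward the earliest trial).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .datatypes import PairedDataset


def mse(predictions: Sequence[float], targets: Sequence[float]) -> float:
    """Mean squared error; errors on length mismatch or empty input."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("mse of empty vectors is undefined")
    return float(np.mean((p - t) ** 2))


def _check_finite(X: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature matrix")


class DrugMeanRegressor(RegressorMixin, BaseEstimator):
    """Per-drug-mean benchmark fit on one-hot drug inputs.

    ``fit`` expects the drug one-hot block only (pairs x n_drugs); the
    prediction for a row is the training mean of its drug's targets, and the
    global training mean when that drug had no training rows.  Predictions
    never depend on the cell line.
    """

    def __init__(self, vocabulary: list[str] | None = None):
        self.vocabulary = vocabulary

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("cannot fit the drug-average benchmark on 0 pairs")
        members = X > 0.5
        counts = members.sum(axis=0)
        means = np.full(X.shape[1], np.nan)
        for j in np.flatnonzero(counts):
            means[j] = np.mean(y[members[:, j]])
        self.column_means_ = means
        self.column_counts_ = counts
        self.global_mean_ = float(y.mean())
        if self.vocabulary is not None:
            if len(self.vocabulary) != X.shape[1]:
                raise ValueError("vocabulary length != one-hot width")
            self.per_drug_mean_ = {
                d: float(means[j])
                for j, d in enumerate(self.vocabulary)
                if counts[j] > 0
            }
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        idx = X.argmax(axis=1)
        out = self.column_means_[idx]
        return np.where(np.isnan(out), self.global_mean_, out)


@dataclass
class ParamRange:
    """Continuous hyperparameter range (linear or log scale)."""

    low: float
    high: float
    scale: str = "linear"
    dtype: type = float

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValueError("empty range: high < low")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")

    def sample(self, rng: np.random.Generator):
        if self.scale == "log":
            value = float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        else:
            value = float(rng.uniform(self.low, self.high))
        return self.dtype(round(value)) if self.dtype is int else value


@dataclass
class HyperparameterSpace:
    """Named parameter ranges/choices plus the trial budget (default 15)."""

    params: dict[str, ParamRange | list[Any]]
    trial_count: int = 15

    def __post_init__(self) -> None:
        if self.trial_count < 1:
            raise ValueError("trial_count must be >= 1")
        for name, spec in self.params.items():
            if isinstance(spec, list) and not spec:
                raise ValueError(f"empty choice list for {name!r}")

    def sample(self, rng: np.random.Generator) -> dict[str, Any]:
        out = {}
        for name, spec in self.params.items():
            if isinstance(spec, ParamRange):
                out[name] = spec.sample(rng)
            else:
                out[name] = spec[rng.integers(len(spec))]
        return out


DEFAULT_GBT_SPACE = HyperparameterSpace(
    params={
        "n_estimators": [2000],
        "max_depth": ParamRange(3, 10, dtype=int),
        "learning_rate": ParamRange(1e-3, 0.3, scale="log"),
        "subsample": ParamRange(0.5, 1.0),
    }
)

DEFAULT_NN_SPACE = HyperparameterSpace(
    params={
        "hidden_layer_sizes": [(256, 128), (128, 64), (64, 32), (64,)],
        "alpha": ParamRange(1e-3, 30.0, scale="log"),
        "learning_rate_init": ParamRange(1e-4, 1e-2, scale="log"),
        "batch_size": [64, 256, 1024],
    }
)


class GradientBoostedLearner(RegressorMixin, BaseEstimator):
    """Boosted-tree regressor with validation-based early stopping.

    A thin policy layer over XGBoost: squared-error objective on the
    concatenated (x_c || x_d) features, boosting rounds capped by
    ``n_estimators`` and halted when validation MSE has not improved for
    ``early_stopping_rounds`` rounds.
    """

    def __init__(
        self,
        n_estimators: int = 300,
        max_depth: int = 6,
        learning_rate: float = 0.1,
        subsample: float = 1.0,
        early_stopping_rounds: int = 20,
        seed: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.early_stopping_rounds = early_stopping_rounds
        self.seed = seed

    def fit(self, X, y, eval_set: tuple[np.ndarray, np.ndarray] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        _check_finite(X)
        booster = XGBRegressor(
            objective="reg:squarederror",
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            tree_method="hist",
            n_jobs=1,
            random_state=self.seed,
            early_stopping_rounds=(
                self.early_stopping_rounds if eval_set is not None else None
            ),
            eval_metric="rmse",
            verbosity=0,
        )
        if eval_set is not None:
            X_val, y_val = eval_set
            _check_finite(np.asarray(X_val, dtype=float))
            booster.fit(X, y, eval_set=[(X_val, y_val)], verbose=False)
            self.stopped_rounds_ = int(getattr(booster, "best_iteration", booster.n_estimators)) + 1
            self.validation_mse_ = mse(booster.predict(X_val), y_val)
        else:
            booster.fit(X, y, verbose=False)
            self.stopped_rounds_ = self.n_estimators
            self.validation_mse_ = float("nan")
        self.booster_ = booster
        return self

    def predict(self, X):
        return self.booster_.predict(np.asarray(X, dtype=float))


class NeuralNetworkLearner(RegressorMixin, BaseEstimator):
    """Dense feed-forward net with explicit validation early stopping.

    Inputs (omics profile concatenated with the drug one-hot) are
    standardised internally on the training rows; the network is ReLU
    multilayer perceptron trained with Adam on MSE, one epoch per step,
    monitoring MSE on the supplied held-out validation set.  Training stops
    after ``patience`` epochs without improvement and the best epoch's
    weights are restored.  With a fixed seed and thread count, repeated fits
    reproduce the validation MSE to well under 1e-6.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (128, 64),
        alpha: float = 10.0,
        learning_rate_init: float = 3e-3,
        batch_size: int = 256,
        max_epochs: int = 150,
        patience: int = 10,
        seed: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.learning_rate_init = learning_rate_init
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def fit(self, X, y, eval_set: tuple[np.ndarray, np.ndarray] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        _check_finite(X)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        net = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation="relu",
            solver="adam",
            alpha=self.alpha,
            learning_rate_init=self.learning_rate_init,
            batch_size=min(self.batch_size, X.shape[0]),
            random_state=self.seed,
        )
        if eval_set is None:
            # no validation set: plain fixed-epoch training
            net.set_params(max_iter=self.max_epochs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(Xs, y)
            self.net_ = net
            self.stopped_epoch_ = int(net.n_iter_)
            self.validation_mse_ = float("nan")
            return self

        X_val, y_val = eval_set
        X_val = np.asarray(X_val, dtype=float)
        _check_finite(X_val)
        Xv = self.scaler_.transform(X_val)
        best = np.inf
        best_state = None
        best_epoch = 0
        since_improvement = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for epoch in range(1, self.max_epochs + 1):
                net.partial_fit(Xs, y)
                val_mse = mse(net.predict(Xv), y_val)
                if val_mse < best - 1e-12:
                    best = val_mse
                    best_epoch = epoch
                    best_state = (
                        copy.deepcopy(net.coefs_),
                        copy.deepcopy(net.intercepts_),
                    )
                    since_improvement = 0
                else:
                    since_improvement += 1
                    if since_improvement >= self.patience:
                        break
        if best_state is not None:
            net.coefs_, net.intercepts_ = best_state
        self.net_ = net
        self.stopped_epoch_ = best_epoch
        self.validation_mse_ = float(best)
        return self

    def predict(self, X):
        return self.net_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))


@dataclass
class TrainedModel:
    """A fitted learner plus its provenance."""

    kind: str  # benchmark | gbt | nn
    estimator: Any
    params: dict[str, Any] = field(default_factory=dict)
    validation_mse: float = float("nan")
    stopped_epoch_or_rounds: int = 0

    def predict(self, dataset: PairedDataset) -> np.ndarray:
        if self.kind == "benchmark":
            return self.estimator.predict(dataset.drug_inputs)
        return self.estimator.predict(dataset.features())

    def test_mse(self, dataset: PairedDataset) -> float:
        return mse(self.predict(dataset), dataset.targets)


_LEARNERS = {
    "gbt": GradientBoostedLearner,
    "nn": NeuralNetworkLearner,
}


def fit_drug_average(train: PairedDataset) -> TrainedModel:
    """Fit the drug-average benchmark on a paired training set."""
    if len(train) == 0:
        raise ValueError("empty training set")
    est = DrugMeanRegressor(vocabulary=train.drug_vocabulary)
    est.fit(train.drug_inputs, train.targets)
    return TrainedModel(kind="benchmark", estimator=est, validation_mse=float("nan"))


def predict_drug_average(
    model: TrainedModel | DrugMeanRegressor,
    pairs: PairedDataset | list[tuple[str, str]],
) -> np.ndarray:
    """Benchmark predictions for pairs given as a dataset or id list."""
    est = model.estimator if isinstance(model, TrainedModel) else model
    if isinstance(pairs, PairedDataset):
        return est.predict(pairs.drug_inputs)
    vocab = est.vocabulary or []
    position = {d: j for j, d in enumerate(vocab)}
    out = np.empty(len(pairs))
    for i, (_, drug) in enumerate(pairs):
        j = position.get(drug)
        if j is None or est.column_counts_[j] == 0:
            out[i] = est.global_mean_
        else:
            out[i] = est.column_means_[j]
    return out


def _fit_learner(
    kind: str,
    train: PairedDataset,
    val: PairedDataset,
    params: dict[str, Any] | None = None,
    seed: int = 0,
) -> TrainedModel:
    if train.cell_inputs.shape[1] != val.cell_inputs.shape[1]:
        raise ValueError("train and validation feature dimensions differ")
    est = _LEARNERS[kind](**(params or {}))
    if "seed" in est.get_params():
        est.set_params(seed=seed)
    est.fit(train.features(), train.targets, eval_set=(val.features(), val.targets))
    return TrainedModel(
        kind=kind,
        estimator=est,
        params=est.get_params(),
        validation_mse=est.validation_mse_,
        stopped_epoch_or_rounds=getattr(
            est, "stopped_rounds_", getattr(est, "stopped_epoch_", 0)
        ),
    )


def fit_gbt(
    train: PairedDataset,
    val: PairedDataset,
    params: dict[str, Any] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the boosted-tree learner with early stopping on ``val``."""
    return _fit_learner("gbt", train, val, params, seed)


def fit_nn(
    train: PairedDataset,
    val: PairedDataset,
    params: dict[str, Any] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the neural-network learner with early stopping on ``val``."""
    return _fit_learner("nn", train, val, params, seed)


def random_search(
    kind: str,
    space: HyperparameterSpace,
    train: PairedDataset,
    val: PairedDataset,
    seed: int = 0,
) -> TrainedModel:
    """Random hyperparameter search selecting by held-out validation MSE.

    Samples ``space.trial_count`` assignments with a seeded generator, fits
    each, and returns the trial with the smallest validation MSE (earliest
    trial wins ties).  The per-trial log is attached as ``model.trial_log``.
    """
    if kind == "benchmark":
        raise ValueError("the benchmark has no hyperparameters to search")
    rng = np.random.default_rng(seed)
    best: TrainedModel | None = None
    trial_log: list[dict[str, Any]] = []
    failures: list[str] = []
    for trial in range(space.trial_count):
        params = space.sample(rng)
        try:
            model = _fit_learner(kind, train, val, params, seed=seed)
        except Exception as exc:  # noqa: BLE001 - aggregate and report
            failures.append(f"trial {trial}: {exc}")
            continue
        trial_log.append(
            {"trial": trial, "params": params, "validation_mse": model.validation_mse}
        )
        if best is None or model.validation_mse < best.validation_mse:
            best = model
    if best is None:
        raise RuntimeError("all trials failed: " + "; ".join(failures))
    best.trial_log = trial_log  # type: ignore[attr-defined]
    return best
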