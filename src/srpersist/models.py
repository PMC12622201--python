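"""Downstream learners and evaluation metrics.

Two learners consume the commutative-algebra embedding:

* **CATree** -- an ensemble of gradient-boosted tree models (scikit-learn
  ``GradientBoosting*``), trained ``repetitions`` times with independent
  seeds and averaged, suited to small mutation datasets.
* **CANet** -- a plain fully connected feed-forward network
  (scikit-learn ``MLP*``): six hidden layers of equal width, Adam, with a
  regression or classification head depending on the task.

The full-scale hyperparameters (20000 estimators / width 15000) are
the config defaults; ``test_scale()`` constructors give small configs for
fast experimentation and CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import pearsonr
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.neural_network import MLPClassifier, MLPRegressor

TASKS = ("binary", "regression", "multiclass-3")

#: solubility-change class encoding
SOLUBILITY_CLASSES = {"decrease": 0, "increase": 1, "unchanged": 2}


@dataclass
class CATreeConfig:
    """Gradient-boosted tree ensemble hyperparameters.

    Defaults are the full-scale operating point: 20000 estimators, depth 7,
    min split 3, learning rate 0.05, square-root feature sampling, 0.4
    subsample, averaged over 10 repetitions.
    """

    n_estimators: int = 20000
    max_depth: int = 7
    min_samples_split: int = 3
    learning_rate: float = 0.05
    max_features: str = "sqrt"
    subsample: float = 0.4
    repetitions: int = 10
    seed: int = 0

    @classmethod
    def test_scale(cls, seed: int = 0) -> "CATreeConfig":
        """Small config for fast runs: ensemble size reduced (estimators,
        repetitions), all per-tree settings kept at the defaults."""
        return cls(n_estimators=200, repetitions=3, seed=seed)


@dataclass
class CANetConfig:
    """Feed-forward network hyperparameters.

    Defaults: six hidden layers of 15000 neurons, learning rate 0.001,
    200 epochs; batch size 32 for regression (stability-change) tasks and
    50 for the 3-class solubility task.
    """

    task: str = "regression"
    hidden_layers: int = 6
    width: int = 15000
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.batch_size is None:
            self.batch_size = 50 if self.task == "multiclass-3" else 32

    @classmethod
    def test_scale(cls, task: str = "regression", seed: int = 0) -> "CANetConfig":
        """Small config for fast runs (narrow layers, fewer epochs)."""
        return cls(task=task, width=32, epochs=300, seed=seed)


def infer_task(y) -> str:
    """Classify a label vector as binary, multiclass-3 or regression."""
    y = np.asarray(y)
    vals = np.unique(y)
    if np.issubdtype(y.dtype, np.floating) and not np.all(vals == vals.astype(int)):
        return "regression"
    if len(vals) <= 2 and set(vals.astype(int)) <= {0, 1}:
        return "binary"
    if set(vals.astype(int)) <= {0, 1, 2}:
        return "multiclass-3"
    return "regression"


class CATreeEnsemble:
    """Average of independently seeded gradient-boosted tree models."""

    def __init__(self, models, task: str, config: CATreeConfig):
        self.models = models
        self.task = task
        self.config = config

    def predict(self, X) -> np.ndarray:
        if self.task == "regression":
            return np.mean([m.predict(X) for m in self.models], axis=0)
        proba = self.predict_proba(X)
        return self.models[0].classes_[np.argmax(proba, axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        if self.task == "regression":
            raise ValueError("predict_proba is undefined for regression")
        return np.mean([m.predict_proba(X) for m in self.models], axis=0)

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class probability (binary) or predictions (regression)."""
        if self.task == "regression":
            return self.predict(X)
        return self.predict_proba(X)[:, 1] if self.task == "binary" else self.predict_proba(X)


def train_catree(X, y, config: CATreeConfig | None = None, task: str | None = None) -> CATreeEnsemble:
    """Train the gradient-boosted tree ensemble.

    ``repetitions`` models are fit with seeds ``seed, seed+1, ...`` and
    their outputs (predictions or class probabilities) averaged.  The task
    is inferred from the label vector when not given.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    config = config or CATreeConfig()
    if len(X) < config.min_samples_split:
        raise ValueError(
            f"need at least min_samples_split={config.min_samples_split} samples, got {len(X)}"
        )
    task = task or infer_task(y)
    cls = GradientBoostingRegressor if task == "regression" else GradientBoostingClassifier
    models = []
    for rep in range(config.repetitions):
        m = cls(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            learning_rate=config.learning_rate,
            max_features=config.max_features,
            subsample=config.subsample,
            random_state=config.seed + rep,
        )
        m.fit(X, y if task == "regression" else y.astype(int))
        models.append(m)
    return CATreeEnsemble(models, task, config)


def train_canet(X, y, config: CANetConfig):
    """Train the fully connected network for the configured task.

    Returns a fitted scikit-learn estimator with the standard
    ``predict`` / ``predict_proba`` interface.  Training is reproducible
    for a fixed seed on a single device.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    hidden = (config.width,) * config.hidden_layers
    common = dict(
        hidden_layer_sizes=hidden,
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        batch_size=min(config.batch_size, len(X)),
        random_state=config.seed,
        alpha=0.0,
    )
    if config.task == "regression":
        net = MLPRegressor(**common)
        yy = y.astype(float)
    else:
        if config.task == "multiclass-3":
            labels = set(np.unique(y).astype(int))
            if not labels <= set(SOLUBILITY_CLASSES.values()):
                raise ValueError(
                    "multiclass-3 labels must be encoded as "
                    f"{SOLUBILITY_CLASSES} (decrease/increase/unchanged); got {sorted(labels)}"
                )
        net = MLPClassifier(**common)
        yy = y.astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at small epoch counts
        net.fit(X, yy)
    return net


def evaluate(y_true, y_pred, task: str, scores=None) -> dict:
    """Task-appropriate metric table.

    binary -> MCC, AUC (from ``scores`` when given, else from hard
    predictions), F1, balanced accuracy; regression -> Pearson correlation
    and RMSE; multiclass-3 -> normalized accuracy (macro-averaged recall)
    and the generalized squared correlation GC^2 = chi^2 / (N * (K - 1))
    of the confusion matrix.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be aligned")
    if task == "regression":
        rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
        pcc = float(pearsonr(y_true, y_pred)[0]) if len(y_true) > 1 else float("nan")
        return {"pcc": pcc, "rmse": rmse}
    y_true = y_true.astype(int)
    y_pred = y_pred.astype(int)
    if task == "binary":
        out = {
            "mcc": float(matthews_corrcoef(y_true, y_pred)),
            "f1": float(f1_score(y_true, y_pred)),
            "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
        }
        if len(np.unique(y_true)) < 2:
            warnings.warn("single-class y_true: AUC is undefined and omitted", stacklevel=2)
            out["auc"] = None
        else:
            s = np.asarray(scores, dtype=float) if scores is not None else y_pred.astype(float)
            out["auc"] = float(roc_auc_score(y_true, s))
        return out
    if task == "multiclass-3":
        cm = confusion_matrix(y_true, y_pred, labels=[0, 1, 2])
        return {
            "normalized_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
            "accuracy": float(np.trace(cm) / cm.sum()),
            "gc2": _gc2(cm),
        }
    raise ValueError(f"unknown task: {task!r}")


def _gc2(cm: np.ndarray) -> float:
    """Generalized squared correlation: chi^2 of the confusion matrix over N*(K-1)."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    if n == 0:
        return float("nan")
    row = cm.sum(axis=1, keepdims=True)
    col = cm.sum(axis=0, keepdims=True)
    expected = row @ col / n
    mask = expected > 0
    chi2 = float(np.sum((cm[mask] - expected[mask]) ** 2 / expected[mask]))
    k = int(np.sum(cm.sum(axis=1) > 0))
    if k < 2:
        return float("nan")
    return chi2 / (n * (k - 1))
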