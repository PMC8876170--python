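"""Classifiers over fused or deep features: MLP variants and a max-margin model.

Two classifier families mirror the screening system's final stage:

* ``MLPModel`` — a multilayer perceptron (default one hidden layer of 10
  logistic units, softmax output) trained by mini-batch gradient descent on
  either the mean-squared error between one-hot targets and softmax outputs
  (the ``ann`` preset) or the cross-entropy (the ``ffnn`` preset), with
  validation-based early stopping: training halts after 6 consecutive epochs
  without a validation-loss improvement and the returned weights are the
  best-validation checkpoint, never the final epoch.

* ``MaxMarginModel`` — a soft-margin linear support vector machine
  (scikit-learn ``SVC`` behind this module's surface), C = 1 by default.

All features are z-scored with statistics of the *training* partition before
either model sees them; the raw 232-entry fusion mixes histogram masses and
unbounded Haralick statistics whose scales differ by orders of magnitude.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "TrainConfig",
    "TrainingTrace",
    "MLPModel",
    "MaxMarginModel",
    "mse",
    "train_mlp",
    "train_max_margin",
    "predict",
    "early_stop_epoch",
    "save_model",
    "load_model",
]

#: canonical label order: index 1 is the positive (leukemia) class
CLASS_ORDER = ("normal", "leukemia")


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs for the MLP.

    ``objective`` selects the loss: ``mse`` (squared error between one-hot
    targets and softmax outputs) or ``cross_entropy``.
    ``max_validation_failures`` is the early-stopping patience: training halts
    after that many consecutive epochs without validation improvement.
    """

    max_epochs: int = 1000
    max_validation_failures: int = 6
    learning_rate: float = 0.5
    batch_size: int = 16  # 0 = full batch
    seed: int = 0
    objective: str = "mse"
    hidden_layers: tuple = (10,)

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.max_validation_failures < 1:
            raise ValueError("max_validation_failures must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.objective not in ("mse", "cross_entropy"):
            raise ValueError("objective must be 'mse' or 'cross_entropy'")


@dataclass
class TrainingTrace:
    """Per-epoch record of the MLP fit."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    test_loss: list = field(default_factory=list)
    gradient_norm: list = field(default_factory=list)
    failure_counter: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


@dataclass
class _Scaler:
    mean: np.ndarray
    std: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    @classmethod
    def fit(cls, x: np.ndarray) -> "_Scaler":
        std = x.std(axis=0)
        return cls(mean=x.mean(axis=0), std=np.where(std > 1e-12, std, 1.0))


@dataclass
class MLPModel:
    """Perceptron weights plus the feature scaler fitted on the training split."""

    weights: list
    biases: list
    scaler: _Scaler
    objective: str

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if i < len(self.weights) - 1:
                a = 1.0 / (1.0 + np.exp(-z))  # logistic squashing
            else:
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                a = e / e.sum(axis=1, keepdims=True)
        return a


@dataclass
class MaxMarginModel:
    """Linear soft-margin hyperplane with its scaler and support-vector indices."""

    svc: SVC
    scaler: _Scaler
    support_indices: np.ndarray

    @property
    def input_width(self) -> int:
        return self.scaler.mean.shape[0]

    @property
    def weight_vector(self) -> np.ndarray:
        return self.svc.coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])


def mse(actual, predicted) -> float:
    """Mean squared error ``(1/n) sum (X_i - Y_i)^2`` over all entries."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("mse of empty input is undefined")
    return float(np.mean((a - p) ** 2))


def early_stop_epoch(val_losses, patience: int) -> int:
    """Index of the epoch at which training halts under the patience rule.

    The failure counter increments on every epoch whose validation loss does
    not improve on the best seen so far and resets on improvement; training
    halts once the counter reaches ``patience``.  Returns ``len(val_losses)``
    when the sequence never triggers the rule.
    """
    best = np.inf
    failures = 0
    for e, loss in enumerate(val_losses):
        if loss < best:
            best = loss
            failures = 0
        else:
            failures += 1
            if failures >= patience:
                return e
    return len(val_losses)


def _check_two_classes(y: np.ndarray, where: str) -> None:
    if np.unique(y).size < 2:
        raise ValueError(f"{where} must contain both classes")


def _loss(y_onehot: np.ndarray, probs: np.ndarray, objective: str) -> float:
    if objective == "mse":
        return mse(y_onehot, probs)
    return float(-np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1)))


def train_mlp(features, labels, partitions, config: TrainConfig = TrainConfig()
              ) -> tuple[MLPModel, TrainingTrace]:
    """Gradient-descent fit with validation-based early stopping.

    ``partitions`` assigns each row to ``train``/``validation``/``test``; the
    trace records all three losses per epoch.  The returned model carries the
    weights of the epoch with minimum validation loss.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    parts = np.asarray(partitions)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    train_idx = parts == "train"
    val_idx = parts == "validation"
    test_idx = parts == "test"
    _check_two_classes(y[train_idx], "training partition")

    scaler = _Scaler.fit(x[train_idx])
    xs = scaler.transform(x)
    y_onehot = np.eye(2)[y]

    rng = np.random.default_rng(config.seed)
    sizes = [x.shape[1], *config.hidden_layers, 2]
    weights = [rng.normal(0.0, np.sqrt(1.0 / sizes[i]), (sizes[i], sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    model = MLPModel(weights=weights, biases=biases, scaler=scaler,
                     objective=config.objective)

    xt, yt = xs[train_idx], y_onehot[train_idx]
    trace = TrainingTrace()
    best_val = np.inf
    best_state = None
    failures = 0
    n = xt.shape[0]
    batch = config.batch_size if config.batch_size > 0 else n

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        grad_norm_sq = 0.0
        for start in range(0, n, batch):
            idx = order[start: start + batch]
            xb, yb = xt[idx], yt[idx]
            # forward with caches
            acts = [xb]
            a = xb
            for i, (w, b) in enumerate(zip(model.weights, model.biases)):
                z = a @ w + b
                if i < len(model.weights) - 1:
                    a = 1.0 / (1.0 + np.exp(-z))
                else:
                    zz = z - z.max(axis=1, keepdims=True)
                    e = np.exp(zz)
                    a = e / e.sum(axis=1, keepdims=True)
                acts.append(a)
            probs = acts[-1]
            m = xb.shape[0]
            if config.objective == "mse":
                # d/dz of mean((y - p)^2) through softmax
                dp = 2.0 * (probs - yb) / (m * 2)
                dot = np.sum(dp * probs, axis=1, keepdims=True)
                delta = probs * (dp - dot)
            else:
                delta = (probs - yb) / m
            for i in range(len(model.weights) - 1, -1, -1):
                gw = acts[i].T @ delta
                gb = delta.sum(axis=0)
                grad_norm_sq += float((gw**2).sum() + (gb**2).sum())
                if i > 0:
                    da = delta @ model.weights[i].T
                    delta = da * acts[i] * (1.0 - acts[i])
                model.weights[i] -= config.learning_rate * gw
                model.biases[i] -= config.learning_rate * gb

        # epoch bookkeeping
        losses = {}
        for name, idx in (("train", train_idx), ("validation", val_idx), ("test", test_idx)):
            losses[name] = (_loss(y_onehot[idx], model.forward(xs[idx]), config.objective)
                            if idx.any() else float("nan"))
        if not np.isfinite(losses["train"]):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (learning rate {config.learning_rate})")
        trace.train_loss.append(losses["train"])
        trace.val_loss.append(losses["validation"])
        trace.test_loss.append(losses["test"])
        trace.gradient_norm.append(float(np.sqrt(grad_norm_sq)))

        monitor = losses["validation"] if val_idx.any() else losses["train"]
        if monitor < best_val:
            best_val = monitor
            best_state = (copy.deepcopy(model.weights), copy.deepcopy(model.biases))
            trace.best_epoch = epoch
            failures = 0
        else:
            failures += 1
        trace.failure_counter.append(failures)
        if failures >= config.max_validation_failures:
            break
    trace.stopped_epoch = len(trace.train_loss) - 1
    if best_state is not None:
        model.weights, model.biases = best_state
    return model, trace


def train_max_margin(features, labels, C: float = 1.0, kernel: str = "linear",
                     tol: float = 1e-3) -> MaxMarginModel:
    """Soft-margin SVM on standardized features; stores support-vector indices."""
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    _check_two_classes(y, "training data")
    if C <= 0:
        raise ValueError("C must be positive")
    scaler = _Scaler.fit(x)
    svc = SVC(kernel=kernel, C=C, tol=tol)
    svc.fit(scaler.transform(x), y)
    return MaxMarginModel(svc=svc, scaler=scaler,
                          support_indices=svc.support_.copy())


def save_model(model, path) -> None:
    """Portable model container: named arrays plus a kind tag (``.npz``)."""
    if isinstance(model, MLPModel):
        np.savez(path, kind=np.array(f"mlp_{model.objective}"),
                 n_layers=np.array(len(model.weights)),
                 scaler_mean=model.scaler.mean, scaler_std=model.scaler.std,
                 **{f"W{i}": w for i, w in enumerate(model.weights)},
                 **{f"b{i}": b for i, b in enumerate(model.biases)})
    elif isinstance(model, MaxMarginModel):
        if model.svc.kernel != "linear":
            raise ValueError("only linear max-margin models are serializable")
        np.savez(path, kind=np.array("max_margin"),
                 weights=model.weight_vector, bias=np.array(model.bias),
                 support=model.support_indices,
                 scaler_mean=model.scaler.mean, scaler_std=model.scaler.std)
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")


class _LinearMargin:
    """Decision function of a deserialized linear hyperplane."""

    def __init__(self, w: np.ndarray, b: float):
        self.coef_ = w[None, :]
        self.intercept_ = np.array([b])
        self.kernel = "linear"

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return x @ self.coef_[0] + self.intercept_[0]


def load_model(path):
    """Inverse of :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        kind = str(data["kind"])
        scaler = _Scaler(mean=data["scaler_mean"], std=data["scaler_std"])
        if kind.startswith("mlp_"):
            n = int(data["n_layers"])
            return MLPModel(weights=[data[f"W{i}"] for i in range(n)],
                            biases=[data[f"b{i}"] for i in range(n)],
                            scaler=scaler, objective=kind[4:])
        if kind == "max_margin":
            return MaxMarginModel(svc=_LinearMargin(data["weights"], float(data["bias"])),
                                  scaler=scaler, support_indices=data["support"])
    raise ValueError(f"unknown model kind {kind!r} in {path}")


def predict(model, features) -> tuple[np.ndarray, np.ndarray]:
    """Class indices and positive-class scores for a batch of feature rows.

    MLP scores are softmax positive-class probabilities; max-margin scores are
    signed distances to the hyperplane.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[None]
    if x.shape[1] != model.input_width:
        raise ValueError(
            f"feature width {x.shape[1]} does not match model input width {model.input_width}")
    xs = model.scaler.transform(x)
    if isinstance(model, MLPModel):
        probs = model.forward(xs)
        return probs.argmax(axis=1), probs[:, 1]
    scores = model.svc.decision_function(xs)
    return (scores > 0).astype(np.int64), scores
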