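"""From-scratch multilayer perceptron with backpropagation.

Every neuron uses the bipolar sigmoid f(x) = 2 / (1 + exp(-sigma x)) - 1
(range (-1, 1)); inputs are normalized to [-1, 1] with per-feature cutoffs;
targets are 1/0 one-hot codes and the loss is mean squared error, so outputs
approach but never reach the targets — only the argmax matters at
classification time.  Training is full-batch gradient descent with momentum,
reproducible from a seed (weights start uniform in [-0.5, 0.5] scaled by
1/sqrt(fan_in)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan import CLASS_ORDER

__all__ = [
    "TrainConfig",
    "MLPModel",
    "DivergenceError",
    "bipolar_sigmoid",
    "normalize_features",
    "forward",
    "train",
    "classify",
    "hyperparameter_search",
    "loss_and_gradients",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite; try a smaller learning rate."""


def bipolar_sigmoid(x, sigma: float):
    """2 / (1 + exp(-sigma x)) - 1; odd, strictly increasing, range (-1, 1)."""
    return np.tanh(0.5 * sigma * np.asarray(x, dtype=float))


@dataclass
class TrainConfig:
    learning_rate: float = 0.05
    momentum: float = 0.9
    sigma: float = 1.0
    hidden_layers: tuple[int, ...] = (15,)
    max_epochs: int = 10_000
    patience: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")


@dataclass
class MLPModel:
    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]  # weights[l]: (n_in, n_out)
    biases: list[np.ndarray]
    sigma: float
    cutoffs: tuple[np.ndarray, np.ndarray]  # (low, high) per input feature
    class_order: tuple[str, ...] = CLASS_ORDER
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layer_sizes[0] != self.cutoffs[0].size:
            raise ValueError("input size must match cutoff length")
        if self.layer_sizes[-1] != len(self.class_order):
            raise ValueError("output size must match number of classes")
        for W in self.weights:
            if not np.all(np.isfinite(W)):
                raise ValueError("non-finite weights")


def normalize_features(
    x: np.ndarray, cutoffs: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Affine map of [low, high] onto [-1, 1], clipping values outside."""
    low, high = (np.asarray(c, dtype=float) for c in cutoffs)
    if np.any(high <= low):
        bad = int(np.argmax(high <= low))
        raise ValueError(f"degenerate cutoff at feature {bad}: low {low[bad]} >= high {high[bad]}")
    z = 2.0 * (np.asarray(x, dtype=float) - low) / (high - low) - 1.0
    return np.clip(z, -1.0, 1.0)


def percentile_cutoffs(X: np.ndarray, lo: float = 1.0, hi: float = 99.0):
    """Per-feature (p_lo, p_hi) normalization cutoffs from training data."""
    low = np.percentile(X, lo, axis=0)
    high = np.percentile(X, hi, axis=0)
    span = high - low
    span[span < 1e-12] = 1e-12
    return low, low + span


def _forward_pass(weights, biases, sigma, X):
    """Activations at every layer (input included)."""
    acts = [np.asarray(X, dtype=float)]
    for W, b in zip(weights, biases):
        acts.append(bipolar_sigmoid(acts[-1] @ W + b, sigma))
    return acts


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Network outputs for one normalized vector or a batch; values in (-1, 1)."""
    arr = np.asarray(x, dtype=float)
    out = _forward_pass(model.weights, model.biases, model.sigma, np.atleast_2d(arr))[-1]
    return out[0] if arr.ndim == 1 else out


def loss_and_gradients(weights, biases, sigma, X, T, sample_weight=None):
    """MSE loss against 1/0 targets and its analytic gradients.

    The derivative of y = tanh(sigma x / 2) is (sigma / 2) (1 - y^2).
    Exposed so numerical gradient checks can exercise the exact code path
    used in training.
    """
    n = X.shape[0]
    if sample_weight is None:
        sw = np.full(n, 1.0 / n)
    else:
        sw = np.asarray(sample_weight, dtype=float)
        sw = sw / sw.sum()
    acts = _forward_pass(weights, biases, sigma, X)
    Y = acts[-1]
    err = Y - T
    loss = float(np.sum(sw[:, None] * err**2) / T.shape[1])
    grad_W = [None] * len(weights)
    grad_b = [None] * len(biases)
    delta = 2.0 * sw[:, None] * err / T.shape[1] * (0.5 * sigma) * (1.0 - Y**2)
    for l in range(len(weights) - 1, -1, -1):
        grad_W[l] = acts[l].T @ delta
        grad_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ weights[l].T) * (0.5 * sigma) * (1.0 - acts[l] ** 2)
    return loss, grad_W, grad_b


def _init_params(layer_sizes, seed):
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        scale = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-0.5, 0.5, size=(n_in, n_out)) * scale)
        biases.append(rng.uniform(-0.5, 0.5, size=n_out) * scale)
    return weights, biases


def train(
    X: np.ndarray,
    labels,
    cfg: TrainConfig,
    cutoffs: tuple[np.ndarray, np.ndarray] | None = None,
    class_order: tuple[str, ...] = CLASS_ORDER,
    sample_weight=None,
) -> MLPModel:
    """Train an MLP on normalized vectors X and class labels.

    ``X`` must already be normalized to [-1, 1] (``cutoffs`` are stored in
    the model for later use, defaulting to the trivial [-1, 1] identity).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    present = [c for c in class_order if c in labels]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present in the training data")
    class_to_idx = {c: i for i, c in enumerate(class_order)}
    T = np.zeros((X.shape[0], len(class_order)))
    for i, lab in enumerate(labels):
        T[i, class_to_idx[lab]] = 1.0

    layer_sizes = (X.shape[1], *cfg.hidden_layers, len(class_order))
    weights, biases = _init_params(layer_sizes, cfg.seed)
    vel_W = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    if cutoffs is None:
        cutoffs = (np.full(X.shape[1], -1.0), np.full(X.shape[1], 1.0))

    log: list[float] = []
    best = np.inf
    stall = 0
    for _epoch in range(cfg.max_epochs):
        loss, gW, gb = loss_and_gradients(weights, biases, cfg.sigma, X, T, sample_weight)
        if not np.isfinite(loss):
            raise DivergenceError(
                "training loss diverged (NaN/inf); try a smaller learning_rate"
            )
        log.append(loss)
        for l in range(len(weights)):
            vel_W[l] = cfg.momentum * vel_W[l] - cfg.learning_rate * gW[l]
            vel_b[l] = cfg.momentum * vel_b[l] - cfg.learning_rate * gb[l]
            weights[l] = weights[l] + vel_W[l]
            biases[l] = biases[l] + vel_b[l]
        if loss < best - 1e-12:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return MLPModel(
        layer_sizes=layer_sizes,
        weights=weights,
        biases=biases,
        sigma=cfg.sigma,
        cutoffs=cutoffs,
        class_order=tuple(class_order),
        training_log=log,
    )


def classify(model: MLPModel, v: np.ndarray) -> tuple[str, np.ndarray]:
    """Winner-take-all class for one raw (unnormalized) index vector.

    Ties go to the first class in the fixed order (np.argmax convention).
    """
    x = normalize_features(np.asarray(v, dtype=float), model.cutoffs)
    out = forward(model, x)
    return model.class_order[int(np.argmax(out))], out


def hyperparameter_search(
    train_data, test_data, grid: list[TrainConfig],
    cutoffs=None, class_order: tuple[str, ...] = CLASS_ORDER, sample_weight=None,
):
    """Train every config, score by test macro-F1, tie-break on error stability.

    Stability is the variance of the last decile of the training log (lower
    is better).  Returns (best model, report) where the report has one row
    per config.  Divergent configs are recorded and skipped.
    """
    import pandas as pd

    from .evaluation import confusion_matrix, class_metrics

    if not grid:
        raise ValueError("hyperparameter grid is empty")
    Xtr, ytr = train_data
    Xte, yte = test_data
    rows = []
    candidates = []
    for i, cfg in enumerate(grid):
        try:
            model = train(Xtr, ytr, cfg, cutoffs=cutoffs, class_order=class_order,
                          sample_weight=sample_weight)
        except DivergenceError:
            rows.append({"config": i, "diverged": True, "macro_f1": np.nan,
                         "final_loss": np.nan, "stability": np.nan, **_cfg_row(cfg)})
            continue
        preds = [class_order[int(np.argmax(o))]
                 for o in forward(model, np.atleast_2d(Xte))]
        cm = confusion_matrix(yte, preds, class_order=class_order)
        f1s = [class_metrics(cm, c).f1 for c in class_order if c in set(yte)]
        macro_f1 = float(np.mean(f1s))
        tail = model.training_log[-max(1, len(model.training_log) // 10):]
        stability = float(np.var(tail))
        rows.append({"config": i, "diverged": False, "macro_f1": macro_f1,
                     "final_loss": model.training_log[-1], "stability": stability,
                     **_cfg_row(cfg)})
        candidates.append((macro_f1, -stability, -i, model))
    report = pd.DataFrame(rows)
    if not candidates:
        raise DivergenceError("all hyperparameter configs diverged")
    best = max(candidates, key=lambda t: t[:3])
    return best[3], report


def _cfg_row(cfg: TrainConfig) -> dict:
    return {
        "learning_rate": cfg.learning_rate,
        "momentum": cfg.momentum,
        "sigma": cfg.sigma,
        "hidden_layers": str(list(cfg.hidden_layers)),
        "max_epochs": cfg.max_epochs,
        "seed": cfg.seed,
    }
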