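"""BMD regression models.

Features and the reference BMD are z-scored with the sample mean and sample
(n-1) standard deviation.  Two models are fit on the normalized data, both
on the full sample with no train/test split and no regularization:

* a linear model — BMD as a weighted sum of the 45 normalized features plus
  a bias, with weights chosen by minimizing the mean squared error
  (ordinary least squares, minimum-norm solution under rank deficiency);
* a small fully connected network with hidden layers of 8, 8 and 2 ReLU
  units and a single linear output node, trained by full-batch Adam on the
  MSE loss with a fixed seed for bit reproducibility.

Predictions are de-normalized back to g/cm^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NormalizationStats",
    "LinearModel",
    "AnnTrainingConfig",
    "AnnModel",
    "InsufficientDataError",
    "DivergenceError",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "fit_linear",
    "predict_linear",
    "fit_ann",
    "predict_ann",
    "save_model",
    "load_model",
]

ANN_HIDDEN_SIZES = (8, 8, 2)


class InsufficientDataError(ValueError):
    """Raised when too few samples are available to fit."""


class DivergenceError(RuntimeError):
    """Raised when network training produces a non-finite loss."""


@dataclass
class NormalizationStats:
    """Per-column z-score parameters for the features and the target."""

    feature_means: np.ndarray
    feature_stds: np.ndarray
    constant_flags: np.ndarray
    target_mean: float
    target_std: float

    def __post_init__(self) -> None:
        if np.any(self.feature_stds < 0) or self.target_std < 0:
            raise ValueError("standard deviations must be non-negative")
        if not np.array_equal(self.constant_flags, self.feature_stds == 0):
            raise ValueError("constant_flags must mark exactly the zero-variance columns")


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    norm_stats: NormalizationStats
    target_name: str = ""

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.norm_stats.feature_means):
            raise ValueError("weight count must equal feature count")


@dataclass
class AnnTrainingConfig:
    """Full-batch Adam training settings; everything that affects the
    result is here, so a fixed seed gives bit-identical models."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: int | None = None  # None = full batch
    seed: int = 0


@dataclass
class AnnModel:
    """A 45-8-8-2-1 multilayer perceptron with ReLU hidden activations."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    norm_stats: NormalizationStats
    training_config: AnnTrainingConfig
    loss_history: np.ndarray = field(default_factory=lambda: np.array([]))
    target_name: str = ""

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))


def fit_normalization(
    X: np.ndarray, y: np.ndarray, ddof: int = 1
) -> NormalizationStats:
    """Sample mean and sample (n-1) standard deviation per feature column
    and for the target; zero-variance columns are flagged."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    if X.shape[0] < 2:
        raise InsufficientDataError(f"need >= 2 samples, got {X.shape[0]}")
    stds = X.std(axis=0, ddof=ddof)
    return NormalizationStats(
        feature_means=X.mean(axis=0),
        feature_stds=stds,
        constant_flags=stds == 0,
        target_mean=float(y.mean()),
        target_std=float(y.std(ddof=ddof)),
    )


def apply_normalization(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """(x - mean) / std per column; constant columns map to 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(stats.feature_means):
        raise ValueError(
            f"X has {X.shape[1]} columns, stats expect {len(stats.feature_means)}"
        )
    safe_std = np.where(stats.constant_flags, 1.0, stats.feature_stds)
    Xn = (X - stats.feature_means) / safe_std
    Xn[:, stats.constant_flags] = 0.0
    return Xn


def invert_normalization(Xn: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Inverse of :func:`apply_normalization` on non-constant columns."""
    return np.asarray(Xn, dtype=float) * stats.feature_stds + stats.feature_means


def _normalize_target(y: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    if stats.target_std == 0:
        return np.zeros_like(np.asarray(y, dtype=float))
    return (np.asarray(y, dtype=float) - stats.target_mean) / stats.target_std


def _denormalize_target(yn: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return np.asarray(yn, dtype=float) * stats.target_std + stats.target_mean


def fit_linear(
    X: np.ndarray, y: np.ndarray, target_name: str = ""
) -> LinearModel:
    """OLS on normalized features and target.

    Solved with a rank-tolerant least-squares solver, so rank-deficient
    designs (easily reached with 45 features and a small cohort) get the
    minimum-norm solution instead of an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    stats = fit_normalization(X, y)
    Xn = apply_normalization(X, stats)
    yn = _normalize_target(y, stats)
    design = np.hstack([Xn, np.ones((Xn.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(design, yn, rcond=None)
    return LinearModel(
        weights=coef[:-1], bias=float(coef[-1]), norm_stats=stats, target_name=target_name
    )


def predict_linear(model: LinearModel, X_raw: np.ndarray) -> np.ndarray:
    """Normalize, apply weights + bias, de-normalize to g/cm^2."""
    Xn = apply_normalization(np.asarray(X_raw, dtype=float), model.norm_stats)
    yn = Xn @ model.weights + model.bias
    return _denormalize_target(yn, model.norm_stats)


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _forward(
    Xn: np.ndarray, weights: list[np.ndarray], biases: list[np.ndarray]
) -> list[np.ndarray]:
    """Layer activations; ReLU on hidden layers, identity on the output."""
    activations = [Xn]
    h = Xn
    last = len(weights) - 1
    for k, (W, b) in enumerate(zip(weights, biases)):
        z = h @ W + b
        h = z if k == last else np.maximum(z, 0.0)
        activations.append(h)
    return activations


def fit_ann(
    X: np.ndarray,
    y: np.ndarray,
    training_config: AnnTrainingConfig | None = None,
    target_name: str = "",
) -> AnnModel:
    """Train the fixed-architecture MLP with MSE loss.

    Glorot-uniform initialization and full-batch Adam updates, both driven
    by the config seed, make repeated fits bit-identical.  The per-epoch
    loss history is kept on the model.
    """
    cfg = training_config or AnnTrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise InsufficientDataError(f"need >= 10 samples to train the network, got {n}")
    stats = fit_normalization(X, y)
    Xn = apply_normalization(X, stats)
    yn = _normalize_target(y, stats)[:, None]

    sizes = (X.shape[1], *ANN_HIDDEN_SIZES, 1)
    rng = np.random.default_rng(cfg.seed)
    weights = [_glorot_uniform(rng, sizes[k], sizes[k + 1]) for k in range(len(sizes) - 1)]
    # hidden biases start slightly positive: with only 2 units in the last
    # hidden layer, zero-init ReLUs can die early and freeze training at a
    # constant prediction
    n_layers = len(sizes) - 1
    biases = [
        np.full(sizes[k + 1], 0.1 if k < n_layers - 1 else 0.0)
        for k in range(n_layers)
    ]

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate

    batch = n if cfg.batch_size is None else min(cfg.batch_size, n)
    history = np.empty(cfg.epochs)
    step = 0
    for epoch in range(cfg.epochs):
        if batch == n:
            slices = [(Xn, yn)]
        else:
            order = rng.permutation(n)
            slices = [
                (Xn[order[s : s + batch]], yn[order[s : s + batch]])
                for s in range(0, n, batch)
            ]
        for Xb, yb in slices:
            acts = _forward(Xb, weights, biases)
            pred = acts[-1]
            delta = 2.0 * (pred - yb) / Xb.shape[0]
            grads_w: list[np.ndarray] = [None] * len(weights)  # type: ignore[list-item]
            grads_b: list[np.ndarray] = [None] * len(biases)  # type: ignore[list-item]
            for k in range(len(weights) - 1, -1, -1):
                grads_w[k] = acts[k].T @ delta
                grads_b[k] = delta.sum(axis=0)
                if k > 0:
                    delta = (delta @ weights[k].T) * (acts[k] > 0)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for k in range(len(weights)):
                m_w[k] = beta1 * m_w[k] + (1 - beta1) * grads_w[k]
                v_w[k] = beta2 * v_w[k] + (1 - beta2) * grads_w[k] ** 2
                weights[k] -= lr * (m_w[k] / bc1) / (np.sqrt(v_w[k] / bc2) + eps)
                m_b[k] = beta1 * m_b[k] + (1 - beta1) * grads_b[k]
                v_b[k] = beta2 * v_b[k] + (1 - beta2) * grads_b[k] ** 2
                biases[k] -= lr * (m_b[k] / bc1) / (np.sqrt(v_b[k] / bc2) + eps)
        full_pred = _forward(Xn, weights, biases)[-1]
        loss = float(np.mean((full_pred - yn) ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        history[epoch] = loss

    return AnnModel(
        weights=weights,
        biases=biases,
        norm_stats=stats,
        training_config=cfg,
        loss_history=history,
        target_name=target_name,
    )


def predict_ann(model: AnnModel, X_raw: np.ndarray) -> np.ndarray:
    """Forward pass on normalized input, de-normalized to g/cm^2."""
    Xn = apply_normalization(np.asarray(X_raw, dtype=float), model.norm_stats)
    yn = _forward(Xn, model.weights, model.biases)[-1][:, 0]
    return _denormalize_target(yn, model.norm_stats)


# --- JSON serialization -----------------------------------------------------

def _stats_to_dict(stats: NormalizationStats) -> dict:
    return {
        "feature_means": stats.feature_means.tolist(),
        "feature_stds": stats.feature_stds.tolist(),
        "target_mean": stats.target_mean,
        "target_std": stats.target_std,
    }


def _stats_from_dict(d: dict) -> NormalizationStats:
    stds = np.array(d["feature_stds"], dtype=float)
    return NormalizationStats(
        feature_means=np.array(d["feature_means"], dtype=float),
        feature_stds=stds,
        constant_flags=stds == 0,
        target_mean=float(d["target_mean"]),
        target_std=float(d["target_std"]),
    )


def save_model(model: LinearModel | AnnModel, path: str | Path) -> None:
    """Serialize a fitted model (weights, normalization, config) to JSON."""
    if isinstance(model, LinearModel):
        payload = {
            "kind": "linear",
            "target_name": model.target_name,
            "weights": model.weights.tolist(),
            "bias": model.bias,
            "norm_stats": _stats_to_dict(model.norm_stats),
        }
    else:
        payload = {
            "kind": "ann",
            "target_name": model.target_name,
            "layer_sizes": list(model.layer_sizes),
            "weights": [w.tolist() for w in model.weights],
            "biases": [b.tolist() for b in model.biases],
            "norm_stats": _stats_to_dict(model.norm_stats),
            "training_config": vars(model.training_config),
            "loss_history": model.loss_history.tolist(),
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> LinearModel | AnnModel:
    d = json.loads(Path(path).read_text())
    stats = _stats_from_dict(d["norm_stats"])
    if d["kind"] == "linear":
        return LinearModel(
            weights=np.array(d["weights"], dtype=float),
            bias=float(d["bias"]),
            norm_stats=stats,
            target_name=d.get("target_name", ""),
        )
    if d["kind"] == "ann":
        return AnnModel(
            weights=[np.array(w, dtype=float) for w in d["weights"]],
            biases=[np.array(b, dtype=float) for b in d["biases"]],
            norm_stats=stats,
            training_config=AnnTrainingConfig(**d["training_config"]),
            loss_history=np.array(d["loss_history"], dtype=float),
            target_name=d.get("target_name", ""),
        )
    raise ValueError(f"unknown model kind {d.get('kind')!r} in {path}")
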