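"""Three-layer perceptron with adaptive-learning-rate momentum training.

The classifier both wrapper methods evaluate: one input layer, one hidden
layer of hyperbolic-tangent units, and a single log-sigmoid output unit
giving a value in (0, 1).  An output >= 0.5 predicts the positive class
C2 (overweight); < 0.5 predicts C1.

Training is full-batch gradient descent on mean-squared error with a
momentum term and the classical adaptive-learning-rate rule: after each
candidate step, if the error grew by more than ``err_ratio`` the step is
discarded, the learning rate is multiplied by ``lr_dec`` and the momentum
memory is suppressed; otherwise the step is accepted, and when the error
decreased the rate is multiplied by ``lr_inc``.  The defaults
(err_ratio 1.04, lr_dec 0.7, lr_inc 1.05) are the canonical constants of
that scheme; initial learning rate 0.01 and momentum 0.9 are the study
defaults.  Training stops at ``max_epochs`` or when the best error has
improved by less than ``tol`` over ``patience`` consecutive epochs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["NetworkConfig", "TrainedNetwork", "init_network", "train"]

#: hidden-layer sizes scanned by the backward-elimination wrapper
DEFAULT_HIDDEN_GRID = (1, 2, 4, 6, 8)


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and training hyperparameters of the perceptron."""

    n_inputs: int
    n_hidden: int = 2
    init_weight_range: float = 0.5  # weights drawn uniform in [-w, +w]
    lr0: float = 0.01
    mc: float = 0.9
    max_epochs: int = 300
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    err_ratio: float = 1.04
    tol: float = 1e-6
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.init_weight_range < 0:
            raise ValueError("init_weight_range must be >= 0")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 <= self.mc < 1:
            raise ValueError("mc must be in [0, 1)")
        if min(self.lr_inc, self.lr_dec, self.err_ratio) <= 0:
            raise ValueError("adaptive-rate controls must be positive")


def _logsig(z: np.ndarray) -> np.ndarray:
    # numerically stable log-sigmoid, output clipped strictly inside (0, 1)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return np.clip(out, 1e-12, 1.0 - 1e-12)


@dataclass
class TrainedNetwork:
    """Learned weights of the perceptron (possibly untrained)."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    config: NetworkConfig
    error_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output in (0, 1) for one input vector or a matrix."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.config.n_inputs:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects "
                f"{self.config.n_inputs}"
            )
        H = np.tanh(X @ self.W1.T + self.b1)
        out = _logsig(H @ self.w2 + self.b2)
        return out[0] if single else out

    def predict_class(self, X: np.ndarray) -> np.ndarray | str:
        """C2 iff the output is >= 0.5 (ties go to the positive class)."""
        out = self.forward(X)
        if np.isscalar(out) or out.ndim == 0:
            return "C2" if out >= 0.5 else "C1"
        return np.where(out >= 0.5, "C2", "C1")

    def predict01(self, X: np.ndarray) -> np.ndarray:
        """Hard 0/1 predictions (1 = C2) under the 0.5 threshold."""
        return (np.atleast_1d(self.forward(X)) >= 0.5).astype(np.int64)

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": asdict(self.config),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": float(self.b2),
            "error_trajectory": np.asarray(self.error_trajectory).tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedNetwork":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            W1=np.array(d["W1"], dtype=float),
            b1=np.array(d["b1"], dtype=float),
            w2=np.array(d["w2"], dtype=float),
            b2=float(d["b2"]),
            config=NetworkConfig(**d["config"]),
            error_trajectory=np.array(d["error_trajectory"], dtype=float),
        )


def init_network(
    config: NetworkConfig, rng: np.random.Generator | None = None
) -> TrainedNetwork:
    """Draw all weights and biases i.i.d. uniform on [-w, +w]."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = config.init_weight_range
    return TrainedNetwork(
        W1=rng.uniform(-w, w, size=(config.n_hidden, config.n_inputs)),
        b1=rng.uniform(-w, w, size=config.n_hidden),
        w2=rng.uniform(-w, w, size=config.n_hidden),
        b2=float(rng.uniform(-w, w)),
        config=config,
    )


def _mse(net_params, X, y):
    W1, b1, w2, b2 = net_params
    H = np.tanh(X @ W1.T + b1)
    o = _logsig(H @ w2 + b2)
    return float(np.mean((o - y) ** 2))


def gradient(
    net: TrainedNetwork, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic gradient of the mean-squared error w.r.t. all parameters.

    Returns (dW1, db1, dw2, db2) in the same shapes as the weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    H = np.tanh(X @ net.W1.T + net.b1)  # (n, h)
    o = _logsig(H @ net.w2 + net.b2)  # (n,)
    # dE/do for E = mean((o - y)^2); chain through logsig o(1-o)
    dz2 = (2.0 / n) * (o - y) * o * (1.0 - o)  # (n,)
    dw2 = H.T @ dz2
    db2 = float(dz2.sum())
    dH = np.outer(dz2, net.w2) * (1.0 - H**2)  # (n, h)
    dW1 = dH.T @ X
    db1 = dH.sum(axis=0)
    return dW1, db1, dw2, db2


def train(
    config: NetworkConfig,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
) -> TrainedNetwork:
    """Train by batch back-propagation with adaptive learning rate + momentum.

    ``y`` holds 0/1 targets (1 = C2).  Bit-reproducible given
    (config.seed, config, data).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_inputs) matching y")
    if X.shape[1] != config.n_inputs:
        raise ValueError(
            f"X has {X.shape[1]} features but config.n_inputs={config.n_inputs}"
        )
    classes = np.unique(y)
    if classes.size < 2:
        warnings.warn(
            "training targets contain a single class; the network will "
            "learn a constant",
            stacklevel=2,
        )

    net = init_network(config, rng)
    params = [net.W1, net.b1, net.w2, np.array([net.b2])]
    velocity = [np.zeros_like(p) for p in params]
    lr = config.lr0
    err = _mse((params[0], params[1], params[2], params[3][0]), X, y)
    trajectory: list[float] = []  # one entry per epoch, <= max_epochs
    best_err = err
    since_improve = 0

    for _ in range(config.max_epochs):
        net.W1, net.b1, net.w2, net.b2 = (
            params[0],
            params[1],
            params[2],
            float(params[3][0]),
        )
        g = gradient(net, X, y)
        grads = [g[0], g[1], g[2], np.array([g[3]])]
        step = [config.mc * v - lr * gr for v, gr in zip(velocity, grads)]
        cand = [p + s for p, s in zip(params, step)]
        new_err = _mse((cand[0], cand[1], cand[2], cand[3][0]), X, y)
        if not np.isfinite(new_err):
            raise FloatingPointError(
                f"training diverged to non-finite error (lr={lr:.3g}); "
                "reduce lr0 or init_weight_range"
            )
        if err > 0 and new_err / err > config.err_ratio:
            # reject the step: decay the rate, suppress the momentum memory
            lr *= config.lr_dec
            velocity = [np.zeros_like(p) for p in params]
        else:
            if new_err < err:
                lr *= config.lr_inc
            params = cand
            velocity = step
            err = new_err
        trajectory.append(err)
        if best_err - err > config.tol:
            best_err = err
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    net.W1, net.b1, net.w2, net.b2 = (
        params[0],
        params[1],
        params[2],
        float(params[3][0]),
    )
    net.error_trajectory = np.asarray(trajectory)
    return net
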