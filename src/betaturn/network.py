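"""Feed-forward neural network with backprop and MCC-based epoch selection.

One hidden layer of logistic units and two logistic output neurons (one per
class).  Training is online (per-example) gradient descent on the squared
error against a one-hot target, in a freshly shuffled example order each
epoch; after every epoch the Matthews correlation on the held-out test set
at threshold 0.5 is recorded and the weights of the best-MCC epoch are the
ones kept.  The reported score of an example is the positive share of the
two outputs, o_pos / (o_pos + o_neg), which lies in (0, 1).

The per-example update loop is compiled with numba; a plain-numpy gradient
routine (used by the finite-difference correctness test) computes the same
quantities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .metrics import confusion, mcc

__all__ = [
    "TrainConfig",
    "TrainedNetwork",
    "init_network",
    "forward",
    "train_backprop",
    "loss_and_grads",
    "network_to_json",
    "network_from_json",
]

#: Half-width of the uniform weight-initialization interval.
INIT_RANGE = 0.1


@dataclass(frozen=True)
class TrainConfig:
    """Architecture and optimization settings for one network."""

    window: int = 9
    hidden: int = 50
    learning_rate: float = 0.01
    max_epochs: int = 300
    seed: int = 0
    momentum: float = 0.0
    weight_decay: float = 0.0


@dataclass
class Weights:
    w1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (2, hidden)
    b2: np.ndarray  # (2,)

    def copy(self) -> "Weights":
        return Weights(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy())


@dataclass
class TrainedNetwork:
    """A trained network carrying the weights of its best-MCC epoch."""

    weights: Weights
    config: TrainConfig
    n_inputs: int
    best_epoch: int = -1
    leaveout_mcc: float = math.nan
    fold_id: int = -1
    history: list[dict] = field(default_factory=list)
    name: str = ""
    train_chain_ids: tuple[str, ...] = ()


def init_network(config: TrainConfig, n_inputs: int) -> Weights:
    """Small random weights, uniform on +/-INIT_RANGE, fixed by config.seed."""
    rng = np.random.default_rng(config.seed)
    return Weights(
        w1=rng.uniform(-INIT_RANGE, INIT_RANGE, size=(config.hidden, n_inputs)),
        b1=rng.uniform(-INIT_RANGE, INIT_RANGE, size=config.hidden),
        w2=rng.uniform(-INIT_RANGE, INIT_RANGE, size=(2, config.hidden)),
        b2=rng.uniform(-INIT_RANGE, INIT_RANGE, size=2),
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.clip(x, -500, 500, out=out)
    return 1.0 / (1.0 + np.exp(-out))


def _outputs(weights: Weights, x: np.ndarray) -> np.ndarray:
    """Raw two-neuron outputs for a batch (n, d) -> (n, 2)."""
    z1 = _logistic(x @ weights.w1.T + weights.b1)
    return _logistic(z1 @ weights.w2.T + weights.b2)


def forward(network: "TrainedNetwork | Weights", x: np.ndarray) -> np.ndarray:
    """Positive-class score(s) in (0, 1) for one example or a batch."""
    weights = network.weights if isinstance(network, TrainedNetwork) else network
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != weights.w1.shape[1]:
        raise ValueError(
            f"input length {x.shape[1]} does not match architecture "
            f"({weights.w1.shape[1]} inputs)"
        )
    z2 = _outputs(weights, x)
    score = z2[:, 0] / (z2[:, 0] + z2[:, 1])
    return float(score[0]) if single else score


@njit(cache=True)
def _sgd_epoch(x, targets, order, w1, b1, w2, b2, v1, vb1, v2, vb2, lr, mom, decay):
    """One epoch of per-example gradient descent (squared-error loss)."""
    n = order.shape[0]
    h = w1.shape[0]
    d = w1.shape[1]
    total = 0.0
    for k in range(n):
        i = order[k]
        xi = x[i]
        a1 = np.empty(h)
        for j in range(h):
            s = b1[j]
            row = w1[j]
            for m in range(d):
                s += row[m] * xi[m]
            a1[j] = 1.0 / (1.0 + math.exp(-s))
        a2 = np.empty(2)
        for o in range(2):
            s = b2[o]
            for j in range(h):
                s += w2[o, j] * a1[j]
            a2[o] = 1.0 / (1.0 + math.exp(-s))
        d2 = np.empty(2)
        for o in range(2):
            err = a2[o] - targets[i, o]
            total += 0.5 * err * err
            d2[o] = err * a2[o] * (1.0 - a2[o])
        d1 = np.empty(h)
        for j in range(h):
            s = 0.0
            for o in range(2):
                s += w2[o, j] * d2[o]
            d1[j] = s * a1[j] * (1.0 - a1[j])
        for o in range(2):
            g = d2[o]
            for j in range(h):
                v2[o, j] = mom * v2[o, j] - lr * (g * a1[j] + decay * w2[o, j])
                w2[o, j] += v2[o, j]
            vb2[o] = mom * vb2[o] - lr * g
            b2[o] += vb2[o]
        for j in range(h):
            g = d1[j]
            for m in range(d):
                v1[j, m] = mom * v1[j, m] - lr * (g * xi[m] + decay * w1[j, m])
                w1[j, m] += v1[j, m]
            vb1[j] = mom * vb1[j] - lr * g
            b1[j] += vb1[j]
    return total / n


def loss_and_grads(weights: Weights, x: np.ndarray, target: np.ndarray):
    """Squared-error loss and analytic gradients for one example (numpy).

    Mirrors the compiled training kernel; used by the finite-difference
    gradient check.
    """
    z1 = _logistic(weights.w1 @ x + weights.b1)
    z2 = _logistic(weights.w2 @ z1 + weights.b2)
    err = z2 - target
    loss = 0.5 * float(err @ err)
    d2 = err * z2 * (1.0 - z2)
    d1 = (weights.w2.T @ d2) * z1 * (1.0 - z1)
    grads = Weights(
        w1=np.outer(d1, x),
        b1=d1,
        w2=np.outer(d2, z1),
        b2=d2,
    )
    return loss, grads


def train_backprop(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    config: TrainConfig,
    fold_id: int = -1,
) -> TrainedNetwork:
    """Train a network, selecting the epoch with the best test-set MCC.

    `y_*` are binary label vectors.  The test set must contain both classes
    (the Matthews correlation is otherwise undefined).  Fully deterministic
    given (config.seed, data order).
    """
    x_train = np.ascontiguousarray(x_train, dtype=float)
    x_test = np.ascontiguousarray(x_test, dtype=float)
    y_train = np.asarray(y_train).astype(bool)
    y_test = np.asarray(y_test).astype(bool)
    if len(x_train) == 0 or len(x_test) == 0:
        raise ValueError("training and test sets must be nonempty")
    if y_test.all() or (~y_test).all():
        raise ValueError("test set must contain both classes (MCC undefined)")
    targets = np.zeros((len(y_train), 2))
    targets[y_train, 0] = 1.0   # output 0 = positive class
    targets[~y_train, 1] = 1.0
    weights = init_network(config, x_train.shape[1])
    vel = Weights(
        np.zeros_like(weights.w1), np.zeros_like(weights.b1),
        np.zeros_like(weights.w2), np.zeros_like(weights.b2),
    )
    rng = np.random.default_rng(config.seed + 1)
    best = weights.copy()
    best_mcc = -math.inf
    best_epoch = -1
    history = []
    net = TrainedNetwork(weights=weights, config=config, n_inputs=x_train.shape[1],
                         fold_id=fold_id)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train)).astype(np.int64)
        train_err = _sgd_epoch(
            x_train, targets, order,
            weights.w1, weights.b1, weights.w2, weights.b2,
            vel.w1, vel.b1, vel.w2, vel.b2,
            config.learning_rate, config.momentum, config.weight_decay,
        )
        scores = forward(weights, x_test)
        m = mcc(confusion(scores, y_test, 0.5))
        history.append({"epoch": epoch, "train_error": train_err, "test_mcc": m})
        if not math.isnan(m) and m > best_mcc:
            best_mcc = m
            best_epoch = epoch
            best = weights.copy()
    net.weights = best
    net.best_epoch = best_epoch
    net.leaveout_mcc = best_mcc if best_epoch >= 0 else math.nan
    net.history = history
    return net


def network_to_json(net: TrainedNetwork) -> str:
    """Serialize a trained network (architecture + weights) to JSON text."""
    payload = {
        "config": asdict(net.config),
        "n_inputs": net.n_inputs,
        "fold_id": net.fold_id,
        "best_epoch": net.best_epoch,
        "name": net.name,
        "train_chain_ids": list(net.train_chain_ids),
        "leaveout_mcc": None if math.isnan(net.leaveout_mcc) else net.leaveout_mcc,
        "weights": {
            "w1": net.weights.w1.tolist(),
            "b1": net.weights.b1.tolist(),
            "w2": net.weights.w2.tolist(),
            "b2": net.weights.b2.tolist(),
        },
    }
    return json.dumps(payload)


def network_from_json(text: str) -> TrainedNetwork:
    payload = json.loads(text)
    weights = Weights(
        w1=np.array(payload["weights"]["w1"]),
        b1=np.array(payload["weights"]["b1"]),
        w2=np.array(payload["weights"]["w2"]),
        b2=np.array(payload["weights"]["b2"]),
    )
    lomcc = payload["leaveout_mcc"]
    return TrainedNetwork(
        weights=weights,
        config=TrainConfig(**payload["config"]),
        n_inputs=payload["n_inputs"],
        fold_id=payload["fold_id"],
        best_epoch=payload["best_epoch"],
        leaveout_mcc=math.nan if lomcc is None else lomcc,
        name=payload.get("name", ""),
        train_chain_ids=tuple(payload.get("train_chain_ids", ())),
    )
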