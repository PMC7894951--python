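"""Feedforward networks and the Levenberg-Marquardt trainer.

The classifier family is a small grid of fully connected feedforward
networks: 1-3 hidden layers of tanh units (linear outputs), with the first
hidden layer holding 20 or 50 neurons and deeper layers 1/2 and 1/3 of that
(floored).  Targets are one-hot class codes and training minimizes the mean
squared error with damped Gauss-Newton (Levenberg-Marquardt) steps on the
full residual Jacobian, with early stopping on a validation set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkTopology",
    "Network",
    "TrainConfig",
    "TrainedNetwork",
    "build_topologies",
    "init_network",
    "forward",
    "jacobian",
    "train_lm",
    "predict_class",
    "one_hot",
]

HIDDEN_LAYER_COUNTS = (1, 2, 3)
FIRST_LAYER_WIDTHS = (20, 50)


@dataclass(frozen=True)
class NetworkTopology:
    """Layer sizes of one grid member: ``L`` hidden layers, first width
    ``n1``, deeper widths ``n1 // 2`` and ``n1 // 3``."""

    n_hidden_layers: int
    n1: int
    n_inputs: int
    n_outputs: int

    @property
    def hidden_widths(self) -> tuple[int, ...]:
        return (self.n1, self.n1 // 2, self.n1 // 3)[: self.n_hidden_layers]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_widths, self.n_outputs)

    def __post_init__(self):
        if self.n_hidden_layers not in (1, 2, 3):
            raise ValueError("hidden-layer count must be 1, 2 or 3")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")


def build_topologies(n_inputs: int, n_outputs: int) -> list[NetworkTopology]:
    """The six-architecture grid {1,2,3} hidden layers x {20,50} first-layer
    neurons."""
    if n_inputs < 1 or n_outputs < 2:
        raise ValueError("need n_inputs >= 1 and n_outputs >= 2")
    return [
        NetworkTopology(L, n1, n_inputs, n_outputs)
        for L in HIDDEN_LAYER_COUNTS
        for n1 in FIRST_LAYER_WIDTHS
    ]


@dataclass
class Network:
    """Weights of a feedforward net: per layer a (fan_out, fan_in) weight
    matrix and a bias vector.  Hidden activations tanh, output linear."""

    topology: NetworkTopology
    weights: list[np.ndarray] = field(repr=False)
    biases: list[np.ndarray] = field(repr=False)

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([W.ravel(), b]) for W, b in zip(self.weights, self.biases)]
        )

    def unpack(self, theta: np.ndarray) -> None:
        pos = 0
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = theta[pos : pos + W.size].reshape(W.shape)
            pos += W.size
            self.biases[i] = theta[pos : pos + b.size].copy()
            pos += b.size

    def copy(self) -> "Network":
        return Network(
            self.topology,
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
        )

    def to_json(self, path) -> None:
        doc = {
            "topology": {
                "n_hidden_layers": self.topology.n_hidden_layers,
                "n1": self.topology.n1,
                "n_inputs": self.topology.n_inputs,
                "n_outputs": self.topology.n_outputs,
            },
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "Network":
        with open(path) as fh:
            doc = json.load(fh)
        topo = NetworkTopology(**doc["topology"])
        return cls(
            topo,
            [np.asarray(W, dtype=float) for W in doc["weights"]],
            [np.asarray(b, dtype=float) for b in doc["biases"]],
        )


def init_network(topology: NetworkTopology, rng: np.random.Generator) -> Network:
    """Seed-deterministic initialization, uniform in +-1/sqrt(fan_in)."""
    sizes = topology.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return Network(topology, weights, biases)


def _forward_trace(net: Network, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, input first, linear output last."""
    acts = [np.asarray(X, dtype=float)]
    n_layers = len(net.weights)
    for i, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = acts[-1] @ W.T + b
        acts.append(z if i == n_layers - 1 else np.tanh(z))
    return acts


def forward(net: Network, X: np.ndarray) -> np.ndarray:
    """Network outputs, shape (n_samples, n_outputs)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.topology.n_inputs:
        raise ValueError(
            f"input dimension {X.shape[1]} != {net.topology.n_inputs}"
        )
    return _forward_trace(net, X)[-1]


def jacobian(net: Network, X: np.ndarray) -> np.ndarray:
    """Jacobian of all outputs w.r.t. all parameters.

    Returns shape (n_samples * n_outputs, n_params), rows ordered sample-major
    to match ``residuals = (forward(net, X) - T).ravel()``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acts = _forward_trace(net, X)
    S, O = X.shape[0], net.topology.n_outputs
    # delta[s, o, j]: d out_o / d preactivation_j of current layer
    delta = np.broadcast_to(np.eye(O), (S, O, O)).copy()
    blocks: list[np.ndarray] = []
    for layer in range(len(net.weights) - 1, -1, -1):
        a_prev = acts[layer]
        dW = np.einsum("soj,si->soji", delta, a_prev)
        blocks.append(
            np.concatenate(
                [dW.reshape(S * O, -1), delta.reshape(S * O, -1)], axis=1
            )
        )
        if layer > 0:
            delta = np.einsum("soj,ji->soi", delta, net.weights[layer])
            delta = delta * (1.0 - acts[layer] ** 2)[:, None, :]
    return np.concatenate(blocks[::-1], axis=1)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Orthogonal class coding: label c -> unit basis vector e_c."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels outside [0, n_classes)")
    T = np.zeros((labels.size, n_classes))
    T[np.arange(labels.size), labels] = 1.0
    return T


def predict_class(net: Network, X: np.ndarray) -> np.ndarray:
    """Decode one-hot outputs: argmax, ties to the lowest class index."""
    return np.argmax(forward(net, X), axis=1)


@dataclass
class TrainConfig:
    max_iter: int = 1000
    mse_floor: float = 1e-6
    max_val_fails: int = 6
    lambda_init: float = 1e-3
    lambda_max: float = 1e10
    seed: int = 0


@dataclass
class TrainedNetwork:
    network: Network
    n_iterations: int
    final_train_mse: float
    best_val_mse: float
    val_fail_count: int
    stop_reason: str  # max_iter | mse_floor | val_fails | max_damping
    train_mse_history: list[float] = field(default_factory=list, repr=False)
    val_mse_history: list[float] = field(default_factory=list, repr=False)


def _mse(net: Network, X: np.ndarray, T: np.ndarray) -> float:
    r = forward(net, X) - T
    return float(np.mean(r * r))


def _lm_step(J: np.ndarray, r: np.ndarray, lam: float) -> np.ndarray:
    """Solve (J^T J + lam I) step = -J^T r; the dual (Woodbury) form is used
    when residuals are fewer than parameters."""
    n_res, n_par = J.shape
    if n_res < n_par:
        A = J @ J.T
        A[np.diag_indices_from(A)] += lam
        return -J.T @ np.linalg.solve(A, r)
    A = J.T @ J
    A[np.diag_indices_from(A)] += lam
    return np.linalg.solve(A, -(J.T @ r))


def train_lm(
    net: Network,
    X_train: np.ndarray,
    T_train: np.ndarray,
    X_val: np.ndarray,
    T_val: np.ndarray,
    config: TrainConfig | None = None,
) -> TrainedNetwork:
    """Levenberg-Marquardt training with early stopping.

    Each iteration solves the damped normal equations on the full residual
    Jacobian; a step is accepted (damping / 10) when the training MSE
    decreases, otherwise damping is multiplied by 10 and the step retried up
    to the damping cap.  A validation *fail* is an accepted iteration whose
    validation MSE exceeds its running minimum; training stops at 1000
    iterations, an MSE of 1e-6, or six consecutive fails, whichever fires
    first, and the weights at the validation minimum are returned.
    """
    cfg = config or TrainConfig()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    T_train = np.atleast_2d(np.asarray(T_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    T_val = np.atleast_2d(np.asarray(T_val, dtype=float))
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")

    net = net.copy()
    lam = cfg.lambda_init
    train_mse = _mse(net, X_train, T_train)
    val_mse = _mse(net, X_val, T_val)
    best_val = val_mse
    best_net = net.copy()
    fails = 0
    hist_t, hist_v = [train_mse], [val_mse]
    stop = "max_iter"
    n_iter = 0

    for it in range(1, cfg.max_iter + 1):
        n_iter = it
        r = (forward(net, X_train) - T_train).ravel()
        J = jacobian(net, X_train)
        theta = net.pack()
        accepted = False
        while lam <= cfg.lambda_max:
            try:
                step = _lm_step(J, r, lam)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = net.copy()
            trial.unpack(theta + step)
            new_mse = _mse(trial, X_train, T_train)
            if np.isfinite(new_mse) and new_mse < train_mse:
                net = trial
                train_mse = new_mse
                lam = max(lam / 10.0, 1e-20)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            stop = "max_damping"
            break

        val_mse = _mse(net, X_val, T_val)
        hist_t.append(train_mse)
        hist_v.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_net = net.copy()
            fails = 0
        else:
            fails += 1

        if train_mse <= cfg.mse_floor:
            stop = "mse_floor"
            break
        if fails >= cfg.max_val_fails:
            stop = "val_fails"
            break
    else:
        stop = "max_iter"

    return TrainedNetwork(
        network=best_net,
        n_iterations=n_iter,
        final_train_mse=train_mse,
        best_val_mse=best_val,
        val_fail_count=fails,
        stop_reason=stop,
        train_mse_history=hist_t,
        val_mse_history=hist_v,
    )
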