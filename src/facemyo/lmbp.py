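"""Feed-forward classifier trained with Levenberg-Marquardt back-propagation.

The decoder is a fully connected 12-16-2 network with log-sigmoid
activations on both the hidden and output layers.  The four facial
actions are encoded on the two output units as bit pairs:
furrowing brow = (0, 0), raising brow = (0, 1), left smirking = (1, 0),
right smirking = (1, 1); prediction thresholds each output at 0.5.

Training minimizes the batch half sum-of-squares error
E(Q) = 1/2 * sum_m ||P_m - Y_m||^2 over the stacked parameter vector Q
(weights and biases).  Levenberg-Marquardt proposes damped Gauss-Newton
steps

    dQ = -(J^T J + mu I)^{-1} J^T e

where J is the Jacobian of the residual vector e = outputs - targets with
respect to Q, computed by back-propagation.  The damping parameter mu
follows the classical Marquardt schedule: a step is accepted only if it
decreases E (then mu is divided by 10); otherwise mu is multiplied by 10
and the step re-proposed.  mu -> 0 recovers the Gauss-Newton step,
mu -> infinity the (1/mu)-scaled gradient-descent direction.  Training
stops when the step norm falls below ``epsilon``, the error reaches
``goal``, the epoch budget is exhausted, or mu overflows.

An Adam-trained baseline (full-batch first-order moments) on the identical
network and loss is provided for comparison.

Parameter vector order: W1 (hidden x input, row-major), b1, W2
(output x hidden, row-major), b2.  Net input convention: s = W x + b with
activation f(s) = 1 / (1 + exp(-s)); the bias sign is absorbed into the
learned value.  Residuals are e = output - target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .synth_emg import ActionClass

__all__ = [
    "NetworkLayout",
    "NetworkWeights",
    "TrainingConfig",
    "TrainingTrace",
    "LabelCodec",
    "init_network",
    "forward",
    "residuals",
    "mse_error",
    "jacobian",
    "lm_update",
    "train_lmbp",
    "train_adam",
    "predict",
]


def _logsig(s: np.ndarray) -> np.ndarray:
    # Clipped for overflow safety; outputs stay in the open interval (0, 1).
    return 1.0 / (1.0 + np.exp(-np.clip(s, -500.0, 500.0)))


_ACTIVATIONS = {
    "logsig": (_logsig, lambda a: a * (1.0 - a)),
    "identity": (lambda s: s, lambda a: np.ones_like(a)),
}


@dataclass(frozen=True)
class NetworkLayout:
    """Layer sizes and activations (defaults: 12-16-2, log-sigmoid)."""

    n_input: int = 12
    n_hidden: int = 16
    n_output: int = 2
    hidden_activation: str = "logsig"
    output_activation: str = "logsig"

    def __post_init__(self) -> None:
        for name in ("n_input", "n_hidden", "n_output"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("hidden_activation", "output_activation"):
            if getattr(self, name) not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {getattr(self, name)!r}")


@dataclass
class NetworkWeights:
    """Weights and biases of the two-layer network."""

    layout: NetworkLayout
    W1: np.ndarray  # (n_hidden, n_input)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_output, n_hidden)
    b2: np.ndarray  # (n_output,)

    def __post_init__(self) -> None:
        lo = self.layout
        expected = {
            "W1": (lo.n_hidden, lo.n_input),
            "b1": (lo.n_hidden,),
            "W2": (lo.n_output, lo.n_hidden),
            "b2": (lo.n_output,),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def to_vector(self) -> np.ndarray:
        """Stack parameters in the documented order (W1, b1, W2, b2)."""
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def with_vector(self, q: np.ndarray) -> "NetworkWeights":
        """New weights with parameters taken from a stacked vector."""
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_params,):
            raise ValueError(f"expected vector of length {self.n_params}")
        lo = self.layout
        i = 0
        W1 = q[i:i + lo.n_hidden * lo.n_input].reshape(lo.n_hidden, lo.n_input)
        i += W1.size
        b1 = q[i:i + lo.n_hidden]
        i += lo.n_hidden
        W2 = q[i:i + lo.n_output * lo.n_hidden].reshape(lo.n_output, lo.n_hidden)
        i += W2.size
        b2 = q[i:i + lo.n_output]
        return NetworkWeights(lo, W1, b1, W2, b2)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.layout, self.W1.copy(), self.b1.copy(),
                              self.W2.copy(), self.b2.copy())


def init_network(layout: NetworkLayout | None = None, seed: int = 0) -> NetworkWeights:
    """Small symmetric random initialization: U(-0.5, 0.5) / sqrt(fan_in)."""
    layout = layout or NetworkLayout()
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, (layout.n_hidden, layout.n_input))
    W1 /= np.sqrt(layout.n_input)
    b1 = rng.uniform(-0.5, 0.5, layout.n_hidden)
    W2 = rng.uniform(-0.5, 0.5, (layout.n_output, layout.n_hidden))
    W2 /= np.sqrt(layout.n_hidden)
    b2 = rng.uniform(-0.5, 0.5, layout.n_output)
    return NetworkWeights(layout, W1, b1, W2, b2)


def _as_batch(X: np.ndarray, n_features: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != n_features:
        raise ValueError(
            f"input must have {n_features} features, got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains NaN or Inf")
    return X


def forward(
    net: NetworkWeights, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass; returns (outputs, hidden activations), row per sample."""
    X = _as_batch(X, net.layout.n_input)
    f_h = _ACTIVATIONS[net.layout.hidden_activation][0]
    f_o = _ACTIVATIONS[net.layout.output_activation][0]
    H = f_h(X @ net.W1.T + net.b1)
    O = f_o(H @ net.W2.T + net.b2)
    return O, H


def residuals(net: NetworkWeights, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Stacked residual vector e = outputs - targets, sample-major."""
    X = _as_batch(X, net.layout.n_input)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape != (X.shape[0], net.layout.n_output):
        raise ValueError(
            f"targets must have shape {(X.shape[0], net.layout.n_output)}, "
            f"got {Y.shape}"
        )
    O, _ = forward(net, X)
    return (O - Y).ravel()


def mse_error(net: NetworkWeights, X: np.ndarray, Y: np.ndarray) -> float:
    """Batch error E(Q) = 1/2 sum_m ||P_m - Y_m||^2."""
    e = residuals(net, X, Y)
    return 0.5 * float(e @ e)


def jacobian(
    net: NetworkWeights, X: np.ndarray, Y: np.ndarray | None = None
) -> np.ndarray:
    """Residual Jacobian J[r, p] = d e_r / d Q_p via back-propagation.

    Rows stack per-sample, per-output residuals (sample-major); columns
    follow the documented parameter order (W1, b1, W2, b2).  The targets
    do not enter (d e / d Q = d output / d Q) but may be passed for
    interface symmetry with :func:`residuals`.
    """
    X = _as_batch(X, net.layout.n_input)
    lo = net.layout
    M = X.shape[0]
    d_h = _ACTIVATIONS[lo.hidden_activation][1]
    d_o = _ACTIVATIONS[lo.output_activation][1]

    O, H = forward(net, X)
    dO = d_o(O)                                  # (M, n_out)
    dH = d_h(H)                                  # (M, n_hid)

    # Sensitivity of each output unit to each hidden activation, then back
    # through the hidden nonlinearity.
    delta_h = np.einsum("mo,oh->moh", dO, net.W2) * dH[:, None, :]

    J_W1 = np.einsum("moh,mi->mohi", delta_h, X).reshape(
        M, lo.n_output, lo.n_hidden * lo.n_input
    )
    J_b1 = delta_h                                # (M, n_out, n_hid)
    J_W2 = np.zeros((M, lo.n_output, lo.n_output, lo.n_hidden))
    J_b2 = np.zeros((M, lo.n_output, lo.n_output))
    for o in range(lo.n_output):
        J_W2[:, o, o, :] = dO[:, o, None] * H
        J_b2[:, o, o] = dO[:, o]

    J = np.concatenate(
        [
            J_W1,
            J_b1,
            J_W2.reshape(M, lo.n_output, lo.n_output * lo.n_hidden),
            J_b2,
        ],
        axis=2,
    ).reshape(M * lo.n_output, net.n_params)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite values in Jacobian")
    return J


def lm_update(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """Damped Gauss-Newton step: solve (J^T J + mu I) dQ = -J^T e."""
    if mu <= 0:
        raise ValueError("damping parameter mu must be positive")
    J = np.asarray(J, dtype=float)
    e = np.asarray(e, dtype=float)
    A = J.T @ J + mu * np.eye(J.shape[1])
    rhs = -(J.T @ e)
    try:
        c, low = sla.cho_factor(A)
        return sla.cho_solve((c, low), rhs)
    except sla.LinAlgError as exc:  # pragma: no cover - mu > 0 keeps A SPD
        raise np.linalg.LinAlgError(
            f"LM system singular despite damping mu={mu}"
        ) from exc


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyper-parameters for both optimizers.

    ``mu_*`` and ``epsilon`` drive the Levenberg-Marquardt schedule;
    ``learning_rate``/``beta1``/``beta2``/``adam_eps`` are the Adam
    defaults.  ``goal`` is a target on the batch error E(Q) (0 disables).
    """

    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    mu_min: float = 1e-12
    epsilon: float = 1e-6
    max_epochs: int = 1000
    goal: float = 0.0
    learning_rate: float = 1e-2
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.mu_init <= 0 or self.mu_increase <= 0 or self.mu_decrease <= 0:
            raise ValueError("mu parameters must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainingTrace:
    """Per-epoch training history."""

    initial_error: float
    errors: list[float] = field(default_factory=list)
    mu_history: list[float] = field(default_factory=list)
    step_norms: list[float] = field(default_factory=list)
    termination: str = "max_epochs"

    @property
    def n_epochs(self) -> int:
        return len(self.errors)

    @property
    def final_error(self) -> float:
        return self.errors[-1] if self.errors else self.initial_error


def train_lmbp(
    net: NetworkWeights,
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainingConfig | None = None,
) -> tuple[NetworkWeights, TrainingTrace]:
    """Full-batch Levenberg-Marquardt training.

    Every accepted step strictly decreases E(Q); rejected proposals raise
    mu and are retried within the same epoch.
    """
    config = config or TrainingConfig()
    net = net.copy()
    X = _as_batch(X, net.layout.n_input)
    Y = np.asarray(Y, dtype=float)

    E = mse_error(net, X, Y)
    trace = TrainingTrace(initial_error=E)
    mu = config.mu_init

    for _ in range(config.max_epochs):
        if E <= config.goal:
            trace.termination = "goal_reached"
            return net, trace
        e = residuals(net, X, Y)
        J = jacobian(net, X)
        q = net.to_vector()
        accepted = False
        while not accepted:
            dq = lm_update(J, e, mu)
            step_norm = float(np.linalg.norm(dq))
            if step_norm < config.epsilon:
                trace.errors.append(E)
                trace.mu_history.append(mu)
                trace.step_norms.append(step_norm)
                trace.termination = "update_tolerance"
                return net, trace
            candidate = net.with_vector(q + dq)
            E_new = mse_error(candidate, X, Y)
            if E_new < E:
                net, E = candidate, E_new
                # floor keeps J^T J + mu I numerically positive definite
                mu = max(mu * config.mu_decrease, config.mu_min)
                accepted = True
                trace.errors.append(E)
                trace.mu_history.append(mu)
                trace.step_norms.append(step_norm)
            else:
                mu *= config.mu_increase
                if mu > config.mu_max:
                    trace.termination = "mu_overflow"
                    return net, trace
        if E <= config.goal:
            trace.termination = "goal_reached"
            return net, trace
    trace.termination = "max_epochs"
    return net, trace


def train_adam(
    net: NetworkWeights,
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainingConfig | None = None,
) -> tuple[NetworkWeights, TrainingTrace]:
    """Full-batch Adam on the same network and loss (baseline optimizer)."""
    config = config or TrainingConfig()
    net = net.copy()
    X = _as_batch(X, net.layout.n_input)
    Y = np.asarray(Y, dtype=float)

    q = net.to_vector()
    m = np.zeros_like(q)
    v = np.zeros_like(q)
    E = mse_error(net, X, Y)
    trace = TrainingTrace(initial_error=E)

    for t in range(1, config.max_epochs + 1):
        if E <= config.goal:
            trace.termination = "goal_reached"
            return net, trace
        e = residuals(net, X, Y)
        grad = jacobian(net, X).T @ e
        m = config.beta1 * m + (1 - config.beta1) * grad
        v = config.beta2 * v + (1 - config.beta2) * grad**2
        m_hat = m / (1 - config.beta1**t)
        v_hat = v / (1 - config.beta2**t)
        step = config.learning_rate * m_hat / (np.sqrt(v_hat) + config.adam_eps)
        q = q - step
        net = net.with_vector(q)
        E = mse_error(net, X, Y)
        trace.errors.append(E)
        trace.step_norms.append(float(np.linalg.norm(step)))
    trace.termination = "max_epochs"
    return net, trace


class LabelCodec:
    """Bijective mapping between facial actions and 2-bit target vectors."""

    TARGETS: dict[ActionClass, tuple[int, int]] = {
        ActionClass.FURROWING_BROW: (0, 0),
        ActionClass.RAISING_BROW: (0, 1),
        ActionClass.LEFT_SMIRKING: (1, 0),
        ActionClass.RIGHT_SMIRKING: (1, 1),
    }
    _INVERSE = {bits: a for a, bits in TARGETS.items()}

    @classmethod
    def encode(cls, labels) -> np.ndarray:
        """Targets matrix (n, 2) for a sequence of actions (or one action)."""
        if isinstance(labels, (ActionClass, str)):
            return np.array(cls.TARGETS[ActionClass.coerce(labels)], dtype=float)
        return np.array(
            [cls.TARGETS[ActionClass.coerce(a)] for a in labels], dtype=float
        )

    @classmethod
    def decode_bits(cls, bits) -> ActionClass:
        return cls._INVERSE[tuple(int(b) for b in bits)]


def predict(net: NetworkWeights, X: np.ndarray) -> list[ActionClass]:
    """Threshold each output unit at 0.5 and decode the bit pair."""
    O, _ = forward(net, X)
    bits = (O >= 0.5).astype(int)
    return [LabelCodec.decode_bits(row) for row in bits]


def network_to_dict(net: NetworkWeights) -> dict:
    """JSON-serializable representation of a network."""
    lo = net.layout
    return {
        "layout": {
            "n_input": lo.n_input,
            "n_hidden": lo.n_hidden,
            "n_output": lo.n_output,
            "hidden_activation": lo.hidden_activation,
            "output_activation": lo.output_activation,
        },
        "W1": net.W1.tolist(),
        "b1": net.b1.tolist(),
        "W2": net.W2.tolist(),
        "b2": net.b2.tolist(),
    }


def network_from_dict(d: dict) -> NetworkWeights:
    layout = NetworkLayout(**d["layout"])
    return NetworkWeights(
        layout,
        np.asarray(d["W1"], dtype=float),
        np.asarray(d["b1"], dtype=float),
        np.asarray(d["W2"], dtype=float),
        np.asarray(d["b2"], dtype=float),
    )
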