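"""From-scratch back-propagation regressor (4 -> H -> 1) and split protocol.

A three-layer feedforward network with a tanh hidden layer and identity
output maps the (standardized) image features to a (standardized)
refractive index.  Training is full-batch gradient descent with classical
momentum on the mean-squared error; gradients are derived analytically and
unit-checked against central finite differences.  Features and labels are
z-scored with statistics fitted on the training split only — the raw
features span several orders of magnitude (means vs. summations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, NumericalError, StateError

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "BPNetwork",
    "init_network",
    "train",
    "random_split",
    "r_squared",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings for full-batch gradient descent with momentum.

    The defaults are sized so the standardized training loss reaches its
    plateau on the 45-sample calibration problem: a first-order trainer
    needs the larger step and epoch budget to arrive at the converged
    state that second-order batch trainers (the usual choice for tiny BP
    regression networks) reach in a few dozen iterations.
    """

    learning_rate: float = 0.1
    max_epochs: int = 30000
    tolerance: float = 1e-12
    momentum: float = 0.9
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.max_epochs < 1 or self.tolerance < 0:
            raise ConfigurationError("learning_rate/max_epochs/tolerance must be positive")
        if not 0 <= self.momentum < 1:
            raise ConfigurationError("momentum must lie in [0, 1)")
        if self.restarts < 1:
            raise ConfigurationError("restarts must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition sizes; default the 45/15 split of 60 sets."""

    n_total: int = 60
    n_train: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_train < self.n_total:
            raise ConfigurationError("need 0 < n_train < n_total")

    @property
    def n_test(self) -> int:
        return self.n_total - self.n_train


@dataclass
class BPNetwork:
    """Weights, biases and normalization statistics of the regressor."""

    w1: np.ndarray  # (input_dim, hidden_dim)
    b1: np.ndarray  # (hidden_dim,)
    w2: np.ndarray  # (hidden_dim, 1)
    b2: np.ndarray  # (1,)
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_mean: float | None = None
    y_std: float | None = None

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.w1.shape[1]

    def copy(self) -> "BPNetwork":
        return BPNetwork(*(a.copy() for a in (self.w1, self.b1, self.w2, self.b2)),
                         None if self.x_mean is None else self.x_mean.copy(),
                         None if self.x_std is None else self.x_std.copy(),
                         self.y_mean, self.y_std)

    # -- scaling ---------------------------------------------------------
    def fit_scalers(self, x: np.ndarray, y: np.ndarray) -> None:
        """Fit z-score statistics on (training) data; stds floored at 1e-12."""
        x = np.asarray(x, dtype=float)
        self.x_mean = x.mean(axis=0)
        self.x_std = np.maximum(x.std(axis=0), 1e-12)
        self.y_mean = float(np.mean(y))
        self.y_std = max(float(np.std(y)), 1e-12)

    def _require_scalers(self) -> None:
        if self.x_mean is None or self.y_mean is None:
            raise StateError("scalers not fitted; call fit_scalers or train first")

    # -- forward ---------------------------------------------------------
    def forward_standardized(self, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Hidden activations and standardized output for standardized input."""
        h = np.tanh(xs @ self.w1 + self.b1)
        return h, h @ self.w2 + self.b2

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted RI (RIU) for raw feature rows ``x`` of shape (n, input_dim)."""
        self._require_scalers()
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ConfigurationError(f"expected {self.input_dim} features, got {x.shape[1]}")
        xs = (x - self.x_mean) / self.x_std
        _, ys = self.forward_standardized(xs)
        return (ys[:, 0] * self.y_std) + self.y_mean


def init_network(input_dim: int, hidden_dim: int = 10, seed: int = 0) -> BPNetwork:
    """Seeded symmetric-uniform initialization scaled by fan-in.

    Weights of each layer are drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in));
    biases start at zero.  Equal seeds yield bitwise-equal networks.
    """
    if input_dim < 1 or hidden_dim < 1:
        raise ConfigurationError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(input_dim)
    lim2 = 1.0 / np.sqrt(hidden_dim)
    return BPNetwork(
        w1=rng.uniform(-lim1, lim1, size=(input_dim, hidden_dim)),
        b1=np.zeros(hidden_dim),
        w2=rng.uniform(-lim2, lim2, size=(hidden_dim, 1)),
        b2=np.zeros(1),
    )


def loss_and_gradients(
    net: BPNetwork, xs: np.ndarray, ys: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """MSE loss and analytic parameter gradients on standardized data.

    Exposed so the backward pass can be validated against finite
    differences.
    """
    n = xs.shape[0]
    h, yhat = net.forward_standardized(xs)
    resid = yhat - ys[:, None]
    loss = float(np.mean(resid**2))
    d_yhat = 2.0 * resid / n
    grads = {
        "w2": h.T @ d_yhat,
        "b2": d_yhat.sum(axis=0),
    }
    d_h = d_yhat @ net.w2.T
    d_z1 = d_h * (1.0 - h**2)
    grads["w1"] = xs.T @ d_z1
    grads["b1"] = d_z1.sum(axis=0)
    return loss, grads


def train(
    net: BPNetwork,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[BPNetwork, np.ndarray]:
    """Train on raw features ``x`` and RI labels ``y`` (RIU).

    Fits the z-score scalers on ``(x, y)``, then runs full-batch gradient
    descent with momentum on the standardized MSE.  Stops at ``max_epochs``
    or when the epoch-to-epoch loss change falls below ``tolerance``.

    Returns the trained network and the per-epoch loss history.

    Raises
    ------
    NumericalError
        If the loss becomes non-finite, naming the epoch.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if x.shape[0] == 0:
        raise ConfigurationError("training set is empty")
    net = net.copy()
    net.fit_scalers(x, y)
    xs = (x - net.x_mean) / net.x_std
    ys = (y - net.y_mean) / net.y_std

    velocity = {k: np.zeros_like(getattr(net, k)) for k in ("w1", "b1", "w2", "b2")}
    history = []
    prev_loss = np.inf
    for epoch in range(config.max_epochs):
        loss, grads = loss_and_gradients(net, xs, ys)
        if not np.isfinite(loss):
            raise NumericalError(f"training diverged (non-finite loss) at epoch {epoch}")
        history.append(loss)
        if abs(prev_loss - loss) < config.tolerance:
            break
        prev_loss = loss
        for key, grad in grads.items():
            velocity[key] = config.momentum * velocity[key] - config.learning_rate * grad
            setattr(net, key, getattr(net, key) + velocity[key])
    return net, np.asarray(history)


def random_split(n_total: int, n_train: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random partition into disjoint, exhaustive train/test index sets."""
    if not 0 < n_train < n_total:
        raise ConfigurationError("need 0 < n_train < n_total")
    perm = np.random.default_rng(seed).permutation(n_total)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def r_squared(predicted: np.ndarray, expected: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    ``SS_tot`` is taken about the mean of the expected values; a constant
    expected series has no variance to explain and raises.
    """
    predicted = np.asarray(predicted, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if predicted.shape != expected.shape or predicted.ndim != 1 or len(predicted) < 2:
        raise ConfigurationError("predicted and expected must be equal-length 1-D, length >= 2")
    ss_tot = float(np.sum((expected - expected.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConfigurationError("expected values are constant; R^2 undefined")
    ss_res = float(np.sum((predicted - expected) ** 2))
    return 1.0 - ss_res / ss_tot
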