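"""Extreme Learning Machine head with closed-form and Adam solvers.

An ELM is a single-hidden-layer network whose hidden weights ``W`` and
bias ``b`` are drawn at random once and never updated; only the output
weights ``beta`` are trained. Three solvers are provided:

``pinv``
    the classical minimum-norm least-squares solution
    ``beta = pinv(H) T``;
``ridge``
    the L2-regularized closed form ``beta = (H^T H + lambda I)^-1 H^T T``;
``adam``
    mini-batch optimization of the softmax cross-entropy (or linear MSE)
    objective plus ``lambda ||beta||^2``, with first/second gradient
    moments, bias correction, and early stopping on a validation loss
    that restores the best epoch's weights.

The Adam route with cross-entropy is the "optimum ELM" variant: for
``lambda > 0`` the objective is strictly convex in ``beta``, so the
solver approaches a unique optimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidInputError, NumericError
from .samples import CLASSES

__all__ = [
    "HiddenLayer", "AdamState", "OELMConfig", "ACTIVATIONS",
    "init_hidden", "hidden_output", "solve_pinv", "solve_ridge",
    "adam_step", "solve_adam", "fit", "predict",
    "softmax", "cross_entropy_loss",
]


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _gelu(x):
    from scipy.special import erf
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


ACTIVATIONS = {
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
    "gelu": _gelu,
}


@dataclass(frozen=True)
class HiddenLayer:
    """Frozen random projection ``H = g(X W + b)``.

    ``L = 0`` is the degenerate pass-through layer (``H = X``), letting the
    solvers act directly on the backbone's feature vectors. ``W`` and ``b``
    are write-protected; no solver ever touches them.
    """

    W: np.ndarray | None
    b: np.ndarray | None
    activation: str
    seed: int
    input_dim: int

    @property
    def L(self) -> int:
        return 0 if self.W is None else self.W.shape[1]

    @property
    def width(self) -> int:
        """Output width: ``L``, or ``input_dim`` for the pass-through layer."""
        return self.input_dim if self.W is None else self.W.shape[1]


@dataclass
class AdamState:
    """First/second moment accumulators for one ``beta`` array."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    @classmethod
    def fresh(cls, shape, lr=1e-4, beta1=0.9, beta2=0.999, epsilon=1e-8):
        return cls(m=np.zeros(shape), v=np.zeros(shape), t=0, lr=lr,
                   beta1=beta1, beta2=beta2, epsilon=epsilon)


@dataclass(frozen=True)
class OELMConfig:
    """Hyperparameters of the head and its training loop.

    Training defaults follow the study protocol: batch size 16, learning
    rate 1e-4, a 250-epoch budget with patience 10, cross-entropy loss.
    ``L`` (hidden width) defaults to 1000; ``ridge_lambda`` to 1e-4.
    """

    L: int = 1000
    ridge_lambda: float = 1e-4
    solver: str = "adam"            # pinv | ridge | adam
    loss: str = "cross_entropy"     # cross_entropy | mse
    activation: str = "sigmoid"
    batch_size: int = 16
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    max_epochs: int = 250
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 0:
            raise InvalidConfigError("L must be >= 0")
        if self.ridge_lambda < 0:
            raise InvalidConfigError("lambda must be >= 0")
        if self.solver not in ("pinv", "ridge", "adam"):
            raise InvalidConfigError(f"unknown solver {self.solver!r}")
        if self.loss not in ("cross_entropy", "mse"):
            raise InvalidConfigError(f"unknown loss {self.loss!r}")
        if self.activation not in ACTIVATIONS:
            raise InvalidConfigError(f"unknown activation {self.activation!r}")
        if self.batch_size < 1:
            raise InvalidConfigError("batch_size must be >= 1")
        if self.patience > self.max_epochs:
            raise InvalidConfigError("patience must be <= max_epochs")


def init_hidden(input_dim: int, L: int, activation: str = "sigmoid",
                seed: int = 0) -> HiddenLayer:
    """Draw ``W`` (input_dim x L) and ``b`` uniformly from [-1, 1].

    ``L = 0`` returns the pass-through layer.
    """
    if input_dim < 1:
        raise InvalidConfigError("input_dim must be >= 1")
    if L < 0:
        raise InvalidConfigError("L must be >= 0")
    if activation not in ACTIVATIONS:
        raise InvalidConfigError(f"unknown activation {activation!r}")
    if L == 0:
        return HiddenLayer(W=None, b=None, activation=activation,
                           seed=seed, input_dim=input_dim)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(input_dim, L))
    b = rng.uniform(-1.0, 1.0, size=L)
    W.setflags(write=False)
    b.setflags(write=False)
    return HiddenLayer(W=W, b=b, activation=activation, seed=seed,
                       input_dim=input_dim)


def hidden_output(X: np.ndarray, layer: HiddenLayer) -> np.ndarray:
    """``H = g(X W + b)`` (or ``X`` itself for the pass-through layer)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != layer.input_dim:
        raise InvalidInputError(
            f"feature width {X.shape[1]} != layer input_dim {layer.input_dim}")
    if layer.W is None:
        return X
    return ACTIVATIONS[layer.activation](X @ layer.W + layer.b)


# ---------------------------------------------------------------------------
# closed-form solvers


def solve_pinv(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights ``beta = H^+ T``."""
    H, T = np.atleast_2d(H), np.atleast_2d(T)
    if H.size == 0 or T.size == 0:
        raise InvalidInputError("empty activation or target matrix")
    if H.shape[0] != T.shape[0]:
        raise InvalidInputError("H and T row counts differ")
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return beta


def solve_ridge(H: np.ndarray, T: np.ndarray, lam: float) -> np.ndarray:
    """Ridge closed form ``beta = (H^T H + lambda I)^-1 H^T T``."""
    if lam < 0:
        raise InvalidConfigError("lambda must be >= 0")
    H, T = np.atleast_2d(H), np.atleast_2d(T)
    if H.size == 0:
        raise InvalidInputError("empty activation matrix")
    A = H.T @ H + lam * np.eye(H.shape[1])
    if lam == 0.0:
        return solve_pinv(H, T)     # min-norm solution also covers rank deficiency
    return np.linalg.solve(A, H.T @ T)


# ---------------------------------------------------------------------------
# Adam


def adam_step(beta: np.ndarray, gradient: np.ndarray,
              state: AdamState) -> tuple[np.ndarray, AdamState]:
    """One Adam update with bias-corrected moments; returns new (beta, state)."""
    g = np.asarray(gradient, dtype=np.float64)
    if not np.isfinite(g).all():
        raise NumericError("non-finite gradient")
    if g.shape != beta.shape:
        raise InvalidInputError("gradient/beta shape mismatch")
    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * g
    v = state.beta2 * state.v + (1.0 - state.beta2) * g * g
    m_hat = m / (1.0 - state.beta1 ** t)
    v_hat = v / (1.0 - state.beta2 ** t)
    beta_new = beta - state.lr * m_hat / (np.sqrt(v_hat) + state.epsilon)
    return beta_new, replace(state, m=m, v=v, t=t)


def cross_entropy_loss(H: np.ndarray, T: np.ndarray, beta: np.ndarray,
                       lam: float = 0.0) -> float:
    """Mean softmax cross-entropy of ``H beta`` vs one-hot ``T``, plus
    ``lambda ||beta||^2``."""
    logits = H @ beta
    logz = np.log(np.exp(logits - logits.max(axis=1, keepdims=True))
                  .sum(axis=1)) + logits.max(axis=1)
    ce = float(np.mean(logz - (logits * T).sum(axis=1)))
    return ce + lam * float((beta ** 2).sum())


def _mse_loss(H, T, beta, lam=0.0):
    r = H @ beta - T
    return float(np.mean(r ** 2)) + lam * float((beta ** 2).sum())


def _gradient(H, T, beta, lam, loss):
    n = H.shape[0]
    if loss == "cross_entropy":
        g = H.T @ (softmax(H @ beta) - T) / n
    else:
        g = 2.0 * H.T @ (H @ beta - T) / (n * T.shape[1])
    return g + 2.0 * lam * beta


def objective(H, T, beta, lam, loss="cross_entropy"):
    """The training objective minimized by the Adam solver."""
    return (cross_entropy_loss(H, T, beta, lam) if loss == "cross_entropy"
            else _mse_loss(H, T, beta, lam))


def solve_adam(X_train: np.ndarray, T_train: np.ndarray,
               X_val: np.ndarray, T_val: np.ndarray,
               layer: HiddenLayer, config: OELMConfig,
               ) -> tuple[np.ndarray, pd.DataFrame]:
    """Train ``beta`` by mini-batch Adam with patience-based early stopping.

    Each epoch shuffles the training rows (RNG seeded from the config),
    sweeps mini-batches of ``batch_size``, then logs the training and
    validation objective. Training stops at ``max_epochs`` or once the
    validation loss has not improved for ``patience`` consecutive epochs;
    the returned ``beta`` is the best-validation-epoch snapshot.

    Returns ``(beta, log)`` where ``log`` has one row per epoch with
    columns ``epoch, train_loss, val_loss, is_best``.
    """
    X_train, T_train = np.atleast_2d(X_train), np.atleast_2d(T_train)
    X_val, T_val = np.atleast_2d(X_val), np.atleast_2d(T_val)
    if X_train.size == 0 or X_val.size == 0:
        raise InvalidInputError("empty training or validation set")
    if (T_train.sum(axis=0) == 0).any():
        raise InvalidInputError("a class is absent from the training set")
    H_train = hidden_output(X_train, layer)
    H_val = hidden_output(X_val, layer)
    n, width = H_train.shape
    n_classes = T_train.shape[1]
    lam, loss = config.ridge_lambda, config.loss

    beta = np.zeros((width, n_classes))
    state = AdamState.fresh(beta.shape, lr=config.lr, beta1=config.beta1,
                            beta2=config.beta2, epsilon=config.epsilon)
    rng = np.random.default_rng(config.seed)
    best_val = np.inf
    best_beta = beta.copy()
    since_best = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            g = _gradient(H_train[idx], T_train[idx], beta, lam, loss)
            beta, state = adam_step(beta, g, state)
        train_loss = objective(H_train, T_train, beta, lam, loss)
        val_loss = objective(H_val, T_val, beta, 0.0, loss)
        improved = val_loss < best_val
        if improved:
            best_val = val_loss
            best_beta = beta.copy()
            since_best = 0
        else:
            since_best += 1
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "is_best": improved})
        if since_best >= config.patience:
            break
    return best_beta, pd.DataFrame(rows)


def fit(X_train, T_train, layer: HiddenLayer, config: OELMConfig,
        X_val=None, T_val=None):
    """Dispatch to the configured solver; returns ``(beta, log_or_None)``.

    The closed-form solvers ignore the validation split; ``adam`` requires
    one (falling back to the training set itself when none is given, which
    disables meaningful early stopping but keeps tiny fixtures simple).
    """
    H = hidden_output(np.atleast_2d(X_train), layer)
    if config.solver == "pinv":
        return solve_pinv(H, np.atleast_2d(T_train)), None
    if config.solver == "ridge":
        return solve_ridge(H, np.atleast_2d(T_train), config.ridge_lambda), None
    if X_val is None:
        X_val, T_val = X_train, T_train
    return solve_adam(X_train, T_train, X_val, T_val, layer, config)


def predict(X: np.ndarray, layer: HiddenLayer, beta: np.ndarray,
            classes: tuple[str, ...] = CLASSES):
    """Class labels and softmax score rows for a feature matrix.

    Argmax ties resolve toward the first class in ``classes``
    (``pes_planus`` by default).
    """
    H = hidden_output(X, layer)
    if H.shape[1] != beta.shape[0]:
        raise InvalidInputError("beta width does not match hidden layer")
    scores = softmax(H @ beta)
    labels = [classes[i] for i in np.argmax(scores, axis=1)]
    return labels, scores
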