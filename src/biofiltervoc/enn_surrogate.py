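"""Elman recurrent network surrogate trained by Levenberg-Marquardt.

The surrogate maps the dimensionless biofilm depth X* to the saturation
S*(X*).  Architecture: one hidden layer of logistic units whose previous
activations are copied into a context layer and fed back as extra inputs
(the Elman construction), plus a logistic output unit.  For an input
sequence x(1..T) processed in ascending order with zero initial context:

    h(t) = g(w_hi x(t) + w_hc c(t-1) + b_h),   c(t) = h(t),
    y(t) = sigma(w_oh h(t) + b_o).

Training is least-squares Levenberg-Marquardt on the mean squared error,
with the context sequence treated as exogenous when forming the Jacobian
(teacher-forced truncation -- no backpropagation through time).  The LM
normal system is solved in its dual form ``dw = J^T (J J^T + mu I)^-1 e``
with ``J J^T`` assembled from a Hadamard/Gram factorization of the
Jacobian blocks, so the full T-by-p Jacobian is never formed during
training; :func:`enn_jacobian` builds it explicitly for validation.

The dataset is a single ordered trajectory (uniform points on [0, 1]);
the train/validation/test division selects which outputs are scored, the
forward pass always running over the full sequence.  Biases are included
for hidden and output units (without an output bias a constant target is
unlearnable).  Default initialization is Nguyen-Widrow style -- hidden
sigmoid transition regions tiled across [0, 1] with random centers and
signs -- which is what makes batch LM reliably reach mean absolute
deviations of order 1e-5; plain small-uniform initialization (available
as ``init="uniform"``) stalls in shallow local minima.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import cho_factor, cho_solve

from .reference_solvers import BiofilmProfile

__all__ = [
    "ENNConfig",
    "ENNWeights",
    "TrainingDataset",
    "TrainingRecord",
    "build_dataset",
    "initialize_weights",
    "enn_forward",
    "enn_jacobian",
    "lm_update",
    "lm_step",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logistic_deriv(v):  # derivative expressed through the activation value
    return v * (1.0 - v)


_ACTIVATIONS = {
    "logistic": (_logistic, _logistic_deriv),
    "tanh": (np.tanh, lambda v: 1.0 - v * v),
    "identity": (lambda z: z, lambda v: np.ones_like(v)),
}


@dataclass
class ENNConfig:
    """Network and trainer settings.

    Defaults: 60 hidden/context neurons, logistic activations, at most
    2000 LM iterations on a mean-square-error objective, and a
    0.70/0.15/0.15 train/validation/test division.  ``val_patience`` is
    the number of consecutive accepted steps without validation
    improvement tolerated before stopping (0 disables early stopping).
    """

    n_hidden: int = 60
    n_in: int = 1
    n_out: int = 1
    max_iterations: int = 2000
    mu0: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    val_patience: int = 6
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    hidden_activation: str = "logistic"
    output_activation: str = "logistic"
    init: str = "nguyen_widrow"

    def __post_init__(self) -> None:
        for name in ("n_hidden", "n_in", "n_out", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mu0", "mu_up", "mu_max", "grad_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.mu_down < 1):
            raise ValueError("mu_down must lie in (0, 1)")
        if self.val_patience < 0:
            raise ValueError("val_patience must be >= 0")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split must sum to 1, got {self.split}")
        for act in (self.hidden_activation, self.output_activation):
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")
        if self.init not in ("nguyen_widrow", "uniform"):
            raise ValueError(f"unknown init scheme {self.init!r}")


@dataclass
class ENNWeights:
    """Weight matrices and biases of the Elman network.

    ``w_hi``: hidden-from-input (N, n_in); ``w_hc``: hidden-from-context
    (N, N); ``w_oh``: output-from-hidden (n_out, N); ``b_h``, ``b_o``:
    bias vectors.
    """

    w_hi: np.ndarray
    w_hc: np.ndarray
    w_oh: np.ndarray
    b_h: np.ndarray
    b_o: np.ndarray
    hidden_activation: str = "logistic"
    output_activation: str = "logistic"

    def __post_init__(self) -> None:
        self.w_hi = np.atleast_2d(np.asarray(self.w_hi, dtype=float))
        self.w_hc = np.atleast_2d(np.asarray(self.w_hc, dtype=float))
        self.w_oh = np.atleast_2d(np.asarray(self.w_oh, dtype=float))
        self.b_h = np.asarray(self.b_h, dtype=float).ravel()
        self.b_o = np.asarray(self.b_o, dtype=float).ravel()
        n = self.w_hi.shape[0]
        if self.w_hc.shape != (n, n):
            raise ValueError("w_hc must be square with the hidden width")
        if self.w_oh.shape[1] != n or self.b_h.shape != (n,):
            raise ValueError("inconsistent weight shapes")
        if self.b_o.shape != (self.w_oh.shape[0],):
            raise ValueError("b_o length must equal the output width")
        for arr in (self.w_hi, self.w_hc, self.w_oh, self.b_h, self.b_o):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def n_hidden(self) -> int:
        return self.w_hi.shape[0]

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.w_hi.ravel(),
                self.w_hc.ravel(),
                self.b_h,
                self.w_oh.ravel(),
                self.b_o,
            ]
        )

    def with_vector(self, theta: np.ndarray) -> "ENNWeights":
        """New weights with the same shapes filled from the flat vector."""
        n, ni = self.w_hi.shape
        no = self.w_oh.shape[0]
        i = 0
        w_hi = theta[i : i + n * ni].reshape(n, ni)
        i += n * ni
        w_hc = theta[i : i + n * n].reshape(n, n)
        i += n * n
        b_h = theta[i : i + n]
        i += n
        w_oh = theta[i : i + no * n].reshape(no, n)
        i += no * n
        b_o = theta[i : i + no]
        i += no
        if i != theta.size:
            raise ValueError("vector length does not match weight shapes")
        return ENNWeights(
            w_hi, w_hc, w_oh, b_h, b_o, self.hidden_activation, self.output_activation
        )


@dataclass
class TrainingDataset:
    """Uniform sample of a reference profile with a train/val/test division.

    ``split_index[i]`` is 0 (train), 1 (validation) or 2 (test); the three
    groups partition the indices.
    """

    x_points: np.ndarray
    targets: np.ndarray
    split_index: np.ndarray

    def __post_init__(self) -> None:
        self.x_points = np.asarray(self.x_points, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.split_index = np.asarray(self.split_index, dtype=int)
        if not (
            self.x_points.shape == self.targets.shape == self.split_index.shape
        ):
            raise ValueError("x_points, targets, split_index must share a shape")
        if not set(np.unique(self.split_index)) <= {0, 1, 2}:
            raise ValueError("split_index entries must be 0, 1 or 2")

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split_index == 0)

    @property
    def val_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split_index == 1)

    @property
    def test_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split_index == 2)


@dataclass
class TrainingRecord:
    """Per-run training trace: accepted-step MSE history and stop reason."""

    mse_history: list[float] = field(default_factory=list)
    val_mse_history: list[float] = field(default_factory=list)
    best_val_mse: float = math.inf
    epochs_run: int = 0
    stop_reason: str = "max_iter"


def _largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    short = n - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def build_dataset(
    profile: BiofilmProfile,
    n: int = 1001,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> TrainingDataset:
    """Sample a solved profile at ``n`` uniform points and divide it.

    If the solver grid already is the uniform n-point grid its values are
    used directly, otherwise the profile is interpolated by a cubic
    spline.  Division into train/validation/test uses a seeded random
    permutation with largest-remainder rounding of the split fractions
    (so 1001 points at 0.70/0.15/0.15 give 701/150/150).
    """
    if n < 10:
        raise ValueError(f"need at least 10 dataset points, got {n}")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split must sum to 1, got {split}")
    x = np.linspace(0.0, 1.0, n)
    if profile.grid.size == n and np.allclose(profile.grid, x, atol=1e-12):
        targets = profile.s_values.copy()
    else:
        targets = CubicSpline(profile.grid, profile.s_values)(x)
    sizes = _largest_remainder_sizes(n, split)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    split_index = np.empty(n, dtype=int)
    split_index[perm[: sizes[0]]] = 0
    split_index[perm[sizes[0] : sizes[0] + sizes[1]]] = 1
    split_index[perm[sizes[0] + sizes[1] :]] = 2
    return TrainingDataset(x_points=x, targets=targets, split_index=split_index)


def initialize_weights(config: ENNConfig, rng: np.random.Generator) -> ENNWeights:
    """Draw initial weights for the configured scheme.

    ``nguyen_widrow`` (default): hidden input weights of magnitude
    0.7*N^(1/n_in) with random signs and biases placing each sigmoid's
    transition at a random center in [0, 1]; context weights small
    (uniform/N) so the net starts close to feedforward; output layer
    uniform on [-0.5, 0.5].  ``uniform``: every parameter uniform on
    [-0.5, 0.5].
    """
    n, ni, no = config.n_hidden, config.n_in, config.n_out
    if config.init == "uniform":
        return ENNWeights(
            w_hi=rng.uniform(-0.5, 0.5, (n, ni)),
            w_hc=rng.uniform(-0.5, 0.5, (n, n)),
            w_oh=rng.uniform(-0.5, 0.5, (no, n)),
            b_h=rng.uniform(-0.5, 0.5, n),
            b_o=rng.uniform(-0.5, 0.5, no),
            hidden_activation=config.hidden_activation,
            output_activation=config.output_activation,
        )
    mag = 0.7 * n ** (1.0 / ni)
    direction = rng.choice([-1.0, 1.0], size=(n, ni))
    w_hi = mag * direction / math.sqrt(ni)
    centers = rng.uniform(0.0, 1.0, n)
    b_h = -(w_hi.sum(axis=1)) * centers
    return ENNWeights(
        w_hi=w_hi,
        w_hc=rng.uniform(-0.5, 0.5, (n, n)) / n,
        w_oh=rng.uniform(-0.5, 0.5, (no, n)),
        b_h=b_h,
        b_o=rng.uniform(-0.5, 0.5, no),
        hidden_activation=config.hidden_activation,
        output_activation=config.output_activation,
    )


def _forward_states(weights: ENNWeights, xs: np.ndarray, c0: np.ndarray | None):
    """Run the recurrence; return outputs Y, hidden H and contexts C.

    ``C[t]`` is the context *seen* at step t (i.e. h(t-1)); the final
    context is ``H[-1]``.
    """
    g_h, _ = _ACTIVATIONS[weights.hidden_activation]
    g_o, _ = _ACTIVATIONS[weights.output_activation]
    X = np.atleast_2d(np.asarray(xs, dtype=float))
    if X.shape[0] == 1 and weights.w_hi.shape[1] == 1:
        X = X.reshape(-1, 1)
    T = X.shape[0]
    n = weights.n_hidden
    no = weights.w_oh.shape[0]
    H = np.empty((T, n))
    C = np.empty((T, n))
    Y = np.empty((T, no))
    c = np.zeros(n) if c0 is None else np.asarray(c0, dtype=float).ravel()
    if c.shape != (n,):
        raise ValueError("c0 must have the hidden width")
    w_hi, w_hc, w_oh = weights.w_hi, weights.w_hc, weights.w_oh
    b_h, b_o = weights.b_h, weights.b_o
    for t in range(T):
        h = g_h(w_hi @ X[t] + w_hc @ c + b_h)
        Y[t] = g_o(w_oh @ h + b_o)
        H[t] = h
        C[t] = c
        c = h
    return Y, H, C, X


def enn_forward(
    weights: ENNWeights, x_sequence, c0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run the network over an ordered input sequence.

    Returns ``(outputs, final_context)``; the context starts at zero by
    default and carries the previous step's hidden activations.  Outputs
    of a logistic output unit lie in (0, 1).
    """
    xs = np.asarray(x_sequence, dtype=float)
    if xs.size == 0:
        return np.empty((0,)), np.zeros(weights.n_hidden) if c0 is None else np.asarray(c0)
    if not np.all(np.isfinite(xs)):
        raise ValueError("inputs must be finite")
    Y, H, _, _ = _forward_states(weights, xs, c0)
    out = Y[:, 0] if Y.shape[1] == 1 and xs.ndim == 1 else Y
    return out, H[-1]


def enn_jacobian(
    weights: ENNWeights, x_sequence, c0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit teacher-forced Jacobian dy(t)/dtheta, one row per step.

    The context sequence is treated as exogenous (frozen at the values
    realized during the forward pass), which is the classical truncation
    for Elman training.  Only scalar output networks are supported here.
    Returns ``(J, y)`` with parameter ordering matching
    :meth:`ENNWeights.to_vector`.
    """
    if weights.w_oh.shape[0] != 1:
        raise ValueError("enn_jacobian supports scalar-output networks")
    _, dg_h = _ACTIVATIONS[weights.hidden_activation]
    _, dg_o = _ACTIVATIONS[weights.output_activation]
    Y, H, C, X = _forward_states(weights, np.asarray(x_sequence, dtype=float), c0)
    T, n = H.shape
    ni = X.shape[1]
    y = Y[:, 0]
    d = dg_o(y)  # T
    g = d[:, None] * weights.w_oh[0][None, :] * dg_h(H)  # T x n
    p = n * ni + n * n + n + n + 1
    J = np.empty((T, p))
    J[:, : n * ni] = (g[:, :, None] * X[:, None, :]).reshape(T, n * ni)
    J[:, n * ni : n * ni + n * n] = (g[:, :, None] * C[:, None, :]).reshape(T, n * n)
    J[:, n * ni + n * n : n * ni + n * n + n] = g
    J[:, n * ni + n * n + n : n * ni + n * n + 2 * n] = d[:, None] * H
    J[:, -1] = d
    return J, y


def lm_update(J: np.ndarray, residuals: np.ndarray, mu: float) -> np.ndarray:
    """Solve the damped normal equations ``(J^T J + mu I) dw = J^T e``.

    Uses the dual identity ``dw = J^T (J J^T + mu I)^-1 e`` when there are
    fewer residuals than parameters.  ``mu > 0`` keeps the system positive
    definite; ``mu -> 0`` recovers the Gauss-Newton step and ``mu -> inf``
    a vanishing gradient-descent step.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    J = np.asarray(J, dtype=float)
    e = np.asarray(residuals, dtype=float).ravel()
    if not (np.all(np.isfinite(J)) and np.all(np.isfinite(e))):
        raise ValueError("non-finite Jacobian or residuals")
    m, p = J.shape
    if m < p:
        G = J @ J.T
        z = cho_solve(cho_factor(G + mu * np.eye(m)), e)
        return J.T @ z
    A = J.T @ J
    return cho_solve(cho_factor(A + mu * np.eye(p)), J.T @ e)


def lm_step(
    weights: ENNWeights,
    x_sequence,
    targets,
    mu: float,
    train_idx: np.ndarray | None = None,
) -> tuple[ENNWeights, float]:
    """One Levenberg-Marquardt trial step for the network.

    Residuals are ``target - output`` over the (optionally restricted)
    scored rows of a full-sequence forward pass.  Returns the candidate
    weights and the linearized prediction of the post-step mean squared
    error.
    """
    xs = np.asarray(x_sequence, dtype=float)
    ys = np.asarray(targets, dtype=float)
    J, y = enn_jacobian(weights, xs)
    if train_idx is not None:
        J = J[train_idx]
        e = ys[train_idx] - y[train_idx]
    else:
        e = ys - y
    delta = lm_update(J, e, mu)
    predicted = float(np.mean((e - J @ delta) ** 2))
    return weights.with_vector(weights.to_vector() + delta), predicted


class _GramLM:
    """Dual-form LM engine that never materializes the full Jacobian.

    For the teacher-forced Jacobian the Gram matrix factorizes into
    Hadamard products of T-by-T rank structures:

        J J^T = (g g^T) o (X X^T + C C^T + 1) + (d d^T) o (H H^T + 1)

    where d = sigma'(output), g = d * w_oh * sigma'(hidden).  J^T z and
    J^T e reduce to small matrix products per weight block.
    """

    def __init__(self, X, H, C, d, g, idx):
        self.Xt = X[idx]
        self.Ht = H[idx]
        self.Ct = C[idx]
        self.dt = d[idx]
        self.gt = g[idx]

    def gram(self) -> np.ndarray:
        gg = self.gt @ self.gt.T
        inner = self.Xt @ self.Xt.T + self.Ct @ self.Ct.T + 1.0
        dd = np.outer(self.dt, self.dt)
        return gg * inner + dd * (self.Ht @ self.Ht.T + 1.0)

    def jt_vec(self, z: np.ndarray) -> np.ndarray:
        gz = self.gt * z[:, None]
        dw_hi = gz.T @ self.Xt
        dw_hc = gz.T @ self.Ct
        db_h = self.gt.T @ z
        dz = self.dt * z
        dw_oh = self.Ht.T @ dz
        db_o = float(np.sum(dz))
        return np.concatenate(
            [dw_hi.ravel(), dw_hc.ravel(), db_h, dw_oh, [db_o]]
        )


def train(config: ENNConfig, dataset: TrainingDataset) -> tuple[ENNWeights, TrainingRecord]:
    """Fit the network to the dataset's training points by damped LM.

    Each epoch forms the teacher-forced Gram system on the training rows
    and tries candidate steps with increasing damping ``mu`` until the
    training MSE decreases (then ``mu`` is relaxed by ``mu_down``).  Stops
    on: iteration cap, gradient infinity-norm below ``grad_tol``,
    ``mu`` exceeding ``mu_max``, or ``val_patience`` consecutive accepted
    steps without validation improvement.  A fixed seed makes the run
    bit-reproducible.
    """
    if config.n_in != 1 or config.n_out != 1:
        raise ValueError("training supports scalar-input, scalar-output networks")
    _, dg_h = _ACTIVATIONS[config.hidden_activation]
    _, dg_o = _ACTIVATIONS[config.output_activation]
    xs = dataset.x_points
    ys = dataset.targets
    tr = dataset.train_idx
    va = dataset.val_idx
    if tr.size == 0:
        raise ValueError("dataset has no training points")
    rng = np.random.default_rng(config.seed)
    weights = initialize_weights(config, rng)
    theta = weights.to_vector()

    def forward_mse(th):
        w = weights.with_vector(th)
        Y, H, C, X = _forward_states(w, xs, None)
        y = Y[:, 0]
        return y, H, C, X, float(np.mean((y[tr] - ys[tr]) ** 2))

    y, H, C, X, mse = forward_mse(theta)
    record = TrainingRecord()
    mu = config.mu0
    best_val = math.inf
    bad_val = 0
    for epoch in range(config.max_iterations):
        d = dg_o(y)
        g = d[:, None] * weights.with_vector(theta).w_oh[0][None, :] * dg_h(H)
        engine = _GramLM(X, H, C, d, g, tr)
        e = ys[tr] - y[tr]
        grad = 2.0 * engine.jt_vec(e) / tr.size
        if float(np.max(np.abs(grad))) < config.grad_tol:
            record.stop_reason = "grad_tol"
            break
        G = engine.gram()
        eye = np.eye(tr.size)
        accepted = False
        while mu <= config.mu_max:
            try:
                z = cho_solve(cho_factor(G + mu * eye), e)
            except np.linalg.LinAlgError:  # pragma: no cover - mu*I regularizes
                mu *= config.mu_up
                continue
            cand = theta + engine.jt_vec(z)
            y_c, H_c, C_c, X_c, mse_c = forward_mse(cand)
            if mse_c < mse:
                theta, y, H, C, X, mse = cand, y_c, H_c, C_c, X_c, mse_c
                mu = max(mu * config.mu_down, 1e-20)
                accepted = True
                break
            mu *= config.mu_up
        if not accepted:
            record.stop_reason = "mu_max"
            break
        record.mse_history.append(mse)
        record.epochs_run = epoch + 1
        if va.size:
            val_mse = float(np.mean((y[va] - ys[va]) ** 2))
            record.val_mse_history.append(val_mse)
            if val_mse < best_val:
                best_val = val_mse
                bad_val = 0
            else:
                bad_val += 1
                if config.val_patience and bad_val >= config.val_patience:
                    record.stop_reason = "val_patience"
                    break
        logger.debug("epoch %d: train MSE %.3e, mu %.1e", epoch + 1, mse, mu)
    record.best_val_mse = best_val
    logger.info(
        "LM training stopped after %d epochs (%s); train MSE %.3e",
        record.epochs_run,
        record.stop_reason,
        mse,
    )
    return weights.with_vector(theta), record


def predict(weights: ENNWeights, x_points) -> np.ndarray:
    """Evaluate the surrogate at ascending points in [0, 1].

    The context layer makes outputs order-dependent, so the inputs must be
    sorted ascending (matching the training-time evaluation contract,
    which always runs the full dataset sequence from zero context).
    """
    xs = np.asarray(x_points, dtype=float)
    if xs.size == 0:
        return np.empty(0)
    if np.any(np.diff(xs) < 0):
        raise ValueError("x_points must be ascending (outputs are order-dependent)")
    if np.any((xs < 0) | (xs > 1)):
        raise ValueError("x_points must lie in [0, 1]")
    y, _ = enn_forward(weights, xs)
    return y
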