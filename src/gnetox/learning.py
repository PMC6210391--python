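"""Gradient-descent learning for the recurrent Random Neural Network classifier.

The classifier network has one cell per descriptor (input cells), a block of
hidden cells and a single output cell, fully recurrently connected (no
self-loops).  A sample's descriptor vector ``x`` in [0, 1]^d enters as
exogenous excitatory rates ``Lambda[input_i] = gain * x_i``; the classifier
score is the output cell's steady-state excitation probability.

Training minimises the squared error ``sum_s (q_out^s - y_s)^2`` over the
excitatory and inhibitory weight matrices by full-batch gradient descent.
The gradient of the product-form fixed point is obtained from the standard
linear-system formulation: with ``D_i = r_i + lam_minus_i`` and

    Omega[j, i] = (w+(j, i) - q_i * w-(j, i)) / D_i,

the sensitivity row-vector ``g = dq/dw(u, v)`` solves ``g (I - Omega) =
gamma(u, v)``, where ``gamma`` has the two nonzero entries produced by the
direct dependence of ``lam_plus`` / ``lam_minus`` / ``r`` on the weight.
Weights are projected to >= 0 after every update and firing rates are
recomputed as the weight row sums plus a fixed positive leak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .network import RNNetwork, fixed_point_batch

__all__ = [
    "TrainTrace",
    "SingleClassError",
    "TrainingDivergedError",
    "build_classifier_network",
    "train_rnn",
    "predict_rnn",
    "cv_select_rnn",
    "RNNClassifier",
    "RNNResults",
]

logger = logging.getLogger(__name__)


class SingleClassError(ValueError):
    """Training labels contain only one class."""


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainTrace:
    """Per-epoch training loss (sum of squared errors), training balanced
    accuracy, and the final trained network."""

    loss: np.ndarray
    balanced_accuracy: np.ndarray
    network: RNNetwork


def _check_Xy(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if X.min() < -1e-12 or X.max() > 1 + 1e-12:
        raise ValueError("X must be scaled to [0, 1]")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary (0/1)")
    return X, y


def build_classifier_network(
    n_features: int,
    n_hidden: int,
    seed: int = 0,
    leak: float = 1.0,
    bias: float = 0.2,
    init_scale: float | None = None,
) -> RNNetwork:
    """Random fully-recurrent classifier network: ``n_features`` input
    cells, ``n_hidden`` hidden cells, one output cell.

    Initial weights are uniform[0, init_scale] with ``init_scale``
    defaulting to ``2 / n_cells`` so that initial firing rates are O(1)
    and excitation probabilities start mid-range.  Hidden and output cells
    receive a constant exogenous excitatory drive ``bias``: without it the
    output cell's excitation cannot cross mid-range when descriptor drives
    are weak, and gradients vanish near the all-quiet state.
    """
    n = n_features + n_hidden + 1
    rng = np.random.default_rng(seed)
    s = init_scale if init_scale is not None else 2.0 / n
    w_plus = rng.uniform(0.0, s, size=(n, n))
    w_minus = rng.uniform(0.0, s, size=(n, n))
    np.fill_diagonal(w_plus, 0.0)
    np.fill_diagonal(w_minus, 0.0)
    r = w_plus.sum(axis=1) + w_minus.sum(axis=1) + leak
    Lambda = np.zeros(n)
    Lambda[n_features:] = bias
    return RNNetwork(
        w_plus=w_plus,
        w_minus=w_minus,
        Lambda=Lambda,
        lam=np.zeros(n),
        r=r,
        input_cells=tuple(range(n_features)),
        output_cell=n - 1,
    )


def _resolve_gain(gain: float | None, n_features: int) -> float:
    """Default injection gain min(2.5, 10/d): keeps the total exogenous
    drive O(1) regardless of descriptor count, so wide feature tables do
    not saturate the network."""
    if gain is not None:
        return float(gain)
    return min(2.5, 10.0 / n_features)


def _input_rates(net: RNNetwork, X: np.ndarray, gain: float | None) -> np.ndarray:
    gain = _resolve_gain(gain, len(net.input_cells))
    Lam = np.tile(net.Lambda, (X.shape[0], 1))
    Lam[:, list(net.input_cells)] = gain * X
    return Lam


def _balanced_accuracy(y: np.ndarray, yhat: np.ndarray) -> float:
    pos = y == 1
    neg = ~pos
    sens = np.mean(yhat[pos] == 1) if pos.any() else np.nan
    spec = np.mean(yhat[neg] == 0) if neg.any() else np.nan
    return float((sens + spec) / 2.0)


def train_rnn(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 8,
    lr: float = 0.5,
    epochs: int = 200,
    seed: int = 0,
    gain: float | None = None,
    leak: float = 1.0,
    bias: float = 0.2,
    threshold: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> TrainTrace:
    """Full-batch recurrent gradient descent on the w+/w- matrices.

    Raises :class:`SingleClassError` when ``y`` has a single class and
    :class:`TrainingDivergedError` (naming the epoch) when the loss goes
    non-finite.  Weights stay non-negative after every epoch; firing rates
    track the row sums plus the fixed leak.
    """
    X, y = _check_Xy(X, y)
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError(
            f"training labels contain a single class ({int(classes[0])}); "
            "both classes are required"
        )
    d = X.shape[1]
    net = build_classifier_network(d, n_hidden, seed=seed, leak=leak, bias=bias)
    n = net.n_cells
    out = net.output_cell
    Wp, Wm = net.w_plus, net.w_minus
    r = net.r
    Lam = _input_rates(net, X, gain)
    lam = net.lam

    losses = np.empty(epochs)
    bas = np.empty(epochs)
    Q = None
    eye = np.eye(n)
    for epoch in range(epochs):
        Q, D, _, _, _ = fixed_point_batch(
            Wp, Wm, r, Lam, lam, tol=tol, max_iter=max_iter, q0=Q
        )
        e = Q[:, out] - y
        loss = float((e**2).sum())
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch)
        losses[epoch] = loss
        bas[epoch] = _balanced_accuracy(y, (Q[:, out] >= threshold).astype(int))
        # sensitivity of q_out to every weight, via one linear solve per sample
        Om = (Wp[None, :, :] - Q[:, None, :] * Wm[None, :, :]) / D[:, None, :]
        A = eye[None, :, :] - Om
        rhs = np.zeros((X.shape[0], n))
        rhs[:, out] = 1.0
        v = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]  # columns out of (I-Om)^-1
        b = v / D
        a = e[:, None] * Q  # a[s, u] = e_s * q_u
        c = (a * b).sum(axis=0)  # shared -e q_u v_u / D_u term
        grad_p = np.einsum("su,sv->uv", a, b) - c[:, None]
        grad_m = -np.einsum("su,sv->uv", a, Q * b) - c[:, None]
        m = X.shape[0]
        Wp = np.maximum(Wp - lr * grad_p / m, 0.0)
        Wm = np.maximum(Wm - lr * grad_m / m, 0.0)
        np.fill_diagonal(Wp, 0.0)
        np.fill_diagonal(Wm, 0.0)
        r = Wp.sum(axis=1) + Wm.sum(axis=1) + leak
    final = RNNetwork(
        w_plus=Wp, w_minus=Wm, Lambda=net.Lambda, lam=lam, r=r,
        input_cells=net.input_cells, output_cell=out,
    )
    return TrainTrace(loss=losses, balanced_accuracy=bas, network=final)


def predict_rnn(
    net: RNNetwork,
    X: np.ndarray,
    threshold: float = 0.5,
    gain: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
):
    """Score a batch: output-cell steady-state excitation probability.

    Labels are ``score >= threshold`` (ties go to the active class).  An
    unstable network on some sample leaves the score clamped at 1 and logs
    a warning.
    """
    X = np.asarray(X, dtype=float)
    Lam = _input_rates(net, X, gain)
    Q, _, _, _, stable = fixed_point_batch(
        net.w_plus, net.w_minus, net.r, Lam, net.lam, tol=tol, max_iter=max_iter
    )
    if not stable:
        logger.warning("unstable network on at least one sample; score clamped to 1")
    scores = Q[:, net.output_cell]
    return (scores >= threshold).astype(int), scores


def cv_select_rnn(
    X: np.ndarray,
    y: np.ndarray,
    grid,
    folds: int = 3,
    seed: int = 0,
    **train_kwargs,
):
    """Stratified K-fold selection over (n_hidden, lr, epochs) grid points.

    Selects the point maximising mean validation balanced accuracy; ties
    are broken by smallest ``n_hidden``, then smallest ``epochs``, then
    grid order.  Refits on all data and returns
    ``(best_params, TrainTrace)``.
    """
    X, y = _check_Xy(X, y)
    grid = [dict(g) for g in grid]
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    records = []
    for gi, params in enumerate(grid):
        scores = []
        for tr, va in splits:
            trace = train_rnn(X[tr], y[tr], seed=seed, **params, **train_kwargs)
            yhat, _ = predict_rnn(trace.network, X[va])
            scores.append(_balanced_accuracy(y[va], yhat))
        mean_ba = float(np.nanmean(scores))
        records.append((-mean_ba, params.get("n_hidden", 0), params.get("epochs", 0), gi))
    records.sort()
    best = grid[records[0][3]]
    trace = train_rnn(X, y, seed=seed, **best, **train_kwargs)
    return best, trace


# ---------------------------------------------------------------------------
# Model / Results interface


class RNNClassifier:
    """Random-Neural-Network binary classifier, built from data.

    Parameters
    ----------
    X : (n, d) array
        Descriptors scaled to [0, 1] (continuous physchem plus binary
        fingerprints).
    y : (n,) array
        Binary activity labels.
    n_hidden : int
        Hidden-cell count of the recurrent network.
    gain : float
        Multiplier turning descriptor values into exogenous excitatory
        rates at the input cells.
    leak : float
        Fixed departure rate added to every cell's firing rate; keeps
        ``r > 0`` under weight projection.
    """

    def __init__(self, X, y, n_hidden: int = 8, gain: float | None = None,
                 leak: float = 1.0, bias: float = 0.2):
        self.X, self.y = _check_Xy(X, y)
        self.n_hidden = n_hidden
        self.gain = gain
        self.leak = leak
        self.bias = bias

    @classmethod
    def from_dataframe(cls, df, label_col: str, **kwargs) -> "RNNClassifier":
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(X, y, **kwargs)

    def fit(self, lr: float = 0.5, epochs: int = 200, seed: int = 0) -> "RNNResults":
        trace = train_rnn(
            self.X, self.y, n_hidden=self.n_hidden, lr=lr, epochs=epochs,
            seed=seed, gain=self.gain, leak=self.leak, bias=self.bias,
        )
        return RNNResults(self, trace, {"lr": lr, "epochs": epochs, "seed": seed})

    def fit_cv(self, grid, folds: int = 3, seed: int = 0) -> "RNNResults":
        best, trace = cv_select_rnn(
            self.X, self.y, grid, folds=folds, seed=seed,
            gain=self.gain, leak=self.leak, bias=self.bias,
        )
        return RNNResults(self, trace, dict(best, seed=seed))


class RNNResults:
    """Fitted RNN classifier: trained network, training trace, predictions."""

    def __init__(self, model: RNNClassifier, trace: TrainTrace, params: dict):
        self.model = model
        self.trace = trace
        self.network = trace.network
        self.params = params

    def predict(self, X, threshold: float = 0.5):
        return predict_rnn(self.network, X, threshold=threshold, gain=self.model.gain)

    def summary(self) -> str:
        lines = [
            "Random Neural Network classifier",
            "=" * 40,
            f"cells:              {self.network.n_cells} "
            f"({len(self.network.input_cells)} input, {self.model.n_hidden} hidden, 1 output)",
            f"epochs:             {len(self.trace.loss)}",
            f"final SSE loss:     {self.trace.loss[-1]:.6f}",
            f"final training BA:  {self.trace.balanced_accuracy[-1]:.4f}",
            f"hyperparameters:    {self.params}",
        ]
        return "\n".join(lines)
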