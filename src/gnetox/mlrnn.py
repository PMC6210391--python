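"""Multi-Layer Random Neural Network (MLRNN) classifier.

The MLRNN keeps the original single-cell RNN transfer function and uses it
feed-forward: descriptors are mapped by a fixed non-negative random
projection to 20 input rates, each of 100 hidden RNN cells receives an
excitatory and an inhibitory combination of those rates and responds with
its excitation probability ``min(1, x+ / (r + x-))``, and a ridge
least-squares readout turns the 100 hidden activations into a score.  Only
the readout is trained (the projection and hidden weights are frozen at
initialisation), which makes a fit a single linear solve; the ridge
strength is chosen by stratified cross-validation on balanced accuracy and
results can be averaged over an ensemble of independently initialised
models (20 trials by default).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from sklearn.model_selection import StratifiedKFold

from .learning import SingleClassError, _balanced_accuracy, _check_Xy

__all__ = [
    "MLRNNModel",
    "activation_cell",
    "init_mlrnn",
    "fit_readout",
    "train_mlrnn",
    "predict_mlrnn",
    "MLRNNClassifier",
    "MLRNNResults",
]

DEFAULT_RIDGE_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


def activation_cell(x_plus, x_minus, r):
    """Single RNN-cell transfer: ``min(1, x+ / (r + x-))``.

    ``x_plus``/``x_minus`` are total excitatory/inhibitory arrival rates
    (scalars or arrays, >= 0); ``r`` is the positive firing rate.
    """
    x_plus = np.asarray(x_plus, dtype=float)
    x_minus = np.asarray(x_minus, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("firing rate r must be strictly positive")
    if np.any(x_plus < 0) or np.any(x_minus < 0):
        raise ValueError("arrival rates must be non-negative")
    out = np.minimum(1.0, x_plus / (r + x_minus))
    return out if out.ndim else float(out)


@dataclass
class MLRNNModel:
    """Frozen random projection + RNN hidden layer + linear readout."""

    projection: np.ndarray          # (d, n_inputs), non-negative, columns sum to 1
    w_plus: np.ndarray              # (n_inputs, n_hidden) excitatory rates
    w_minus: np.ndarray             # (n_inputs, n_hidden) inhibitory rates
    r_hidden: float = 1.0
    readout: np.ndarray | None = None   # (n_hidden,)
    bias: float = 0.0
    ridge: float = 0.0
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.projection.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.projection.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w_plus.shape[1]

    def hidden_activations(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        u = X @ self.projection
        return activation_cell(u @ self.w_plus, u @ self.w_minus, self.r_hidden)

    def decision_scores(self, X) -> np.ndarray:
        if self.readout is None:
            raise ValueError("model has no fitted readout; call train_mlrnn first")
        return self.hidden_activations(X) @ self.readout + self.bias

    def save(self, path) -> None:
        np.savez(
            path,
            projection=self.projection, w_plus=self.w_plus, w_minus=self.w_minus,
            r_hidden=self.r_hidden,
            readout=self.readout if self.readout is not None else np.array([]),
            bias=self.bias, ridge=self.ridge, seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "MLRNNModel":
        z = np.load(path)
        readout = z["readout"]
        return cls(
            projection=z["projection"], w_plus=z["w_plus"], w_minus=z["w_minus"],
            r_hidden=float(z["r_hidden"]),
            readout=readout if readout.size else None,
            bias=float(z["bias"]), ridge=float(z["ridge"]), seed=int(z["seed"]),
        )


def init_mlrnn(
    d: int,
    seed: int = 0,
    n_inputs: int = 20,
    n_hidden: int = 100,
    w_max: float = 1.0,
    r_hidden: float = 1.0,
) -> MLRNNModel:
    """Seed-determined MLRNN with the fixed 20-input / 100-hidden structure.

    The projection is sampled uniform[0, 1] and column-normalised (each of
    the 20 input rates is a convex combination of the descriptors); hidden
    excitatory/inhibitory weights are uniform[0, w_max].
    """
    if d < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    projection = rng.uniform(0.0, 1.0, size=(d, n_inputs))
    projection /= projection.sum(axis=0, keepdims=True)
    w_plus = rng.uniform(0.0, w_max, size=(n_inputs, n_hidden))
    w_minus = rng.uniform(0.0, w_max, size=(n_inputs, n_hidden))
    return MLRNNModel(
        projection=projection, w_plus=w_plus, w_minus=w_minus,
        r_hidden=r_hidden, seed=seed,
    )


def fit_readout(H: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Ridge least-squares readout: minimise ``||H b - y||^2 + ridge ||b||^2``.

    Solved through the regularised normal equations
    ``(H'H + ridge I) b = H'y``.  A singular system at ``ridge = 0`` raises
    with a hint to use ``ridge > 0``.
    """
    H = np.asarray(H, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    G = H.T @ H + ridge * np.eye(H.shape[1])
    if ridge == 0.0 and np.linalg.matrix_rank(G) < G.shape[0]:
        raise np.linalg.LinAlgError(
            "normal equations are singular at ridge=0; use ridge > 0"
        )
    return np.linalg.solve(G, H.T @ y)


def _fit_readout_with_bias(H, y, ridge):
    # centre H and y so the intercept is unpenalised
    hm = H.mean(axis=0)
    ym = y.mean()
    beta = fit_readout(H - hm, y - ym, ridge=ridge)
    return beta, float(ym - hm @ beta)


def train_mlrnn(
    X: np.ndarray,
    y: np.ndarray,
    ridge_grid=DEFAULT_RIDGE_GRID,
    folds: int = 3,
    seed: int = 0,
    n_inputs: int = 20,
    n_hidden: int = 100,
    w_max: float = 1.0,
    r_hidden: float = 1.0,
    threshold: float = 0.5,
) -> MLRNNModel:
    """Initialise an MLRNN and fit its readout, choosing the ridge strength
    by stratified cross-validated balanced accuracy (ties favour the larger,
    i.e. more regularised, ridge)."""
    X, y = _check_Xy(X, y)
    if np.unique(y).size < 2:
        raise SingleClassError("training labels contain a single class")
    ridge_grid = list(ridge_grid)
    if not ridge_grid:
        raise ValueError("ridge grid is empty")
    model = init_mlrnn(
        X.shape[1], seed=seed, n_inputs=n_inputs, n_hidden=n_hidden,
        w_max=w_max, r_hidden=r_hidden,
    )
    H = model.hidden_activations(X)
    best_ridge = ridge_grid[0]
    if len(ridge_grid) > 1:
        folds = min(folds, int(np.bincount(y.astype(int)).min()))
        if folds >= 2:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            scores = []
            for ridge in ridge_grid:
                bas = []
                for tr, va in skf.split(H, y):
                    beta, b0 = _fit_readout_with_bias(H[tr], y[tr], ridge)
                    yhat = (H[va] @ beta + b0 >= threshold).astype(int)
                    bas.append(_balanced_accuracy(y[va], yhat))
                scores.append(float(np.nanmean(bas)))
            best = max(range(len(ridge_grid)), key=lambda i: (scores[i], ridge_grid[i]))
            best_ridge = ridge_grid[best]
    beta, b0 = _fit_readout_with_bias(H, y, best_ridge)
    model.readout = beta
    model.bias = b0
    model.ridge = best_ridge
    return model


def predict_mlrnn(model: MLRNNModel, X, threshold: float = 0.5):
    """Labels and scores; label = 1 iff score >= threshold."""
    scores = model.decision_scores(X)
    return (scores >= threshold).astype(int), scores


# ---------------------------------------------------------------------------
# Model / Results interface


class MLRNNClassifier:
    """MLRNN binary classifier built from data, with ensemble averaging.

    The structure is fixed (20 projected inputs, 100 hidden RNN cells);
    ``fit`` trains ``n_trials`` independently initialised models and the
    results object averages their scores (and, for benchmarking, their
    per-trial metrics).
    """

    def __init__(self, X, y, n_inputs: int = 20, n_hidden: int = 100,
                 w_max: float = 1.0, r_hidden: float = 1.0):
        self.X, self.y = _check_Xy(X, y)
        self.n_inputs = n_inputs
        self.n_hidden = n_hidden
        self.w_max = w_max
        self.r_hidden = r_hidden

    @classmethod
    def from_dataframe(cls, df, label_col: str, **kwargs) -> "MLRNNClassifier":
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(X, y, **kwargs)

    def fit(self, ridge_grid=DEFAULT_RIDGE_GRID, folds: int = 3,
            seed: int = 0, n_trials: int = 20) -> "MLRNNResults":
        seeds = [int(s) for s in
                 np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)]
        models = [
            train_mlrnn(
                self.X, self.y, ridge_grid=ridge_grid, folds=folds, seed=s,
                n_inputs=self.n_inputs, n_hidden=self.n_hidden,
                w_max=self.w_max, r_hidden=self.r_hidden,
            )
            for s in seeds
        ]
        return MLRNNResults(self, models)


class MLRNNResults:
    """Fitted MLRNN ensemble: per-trial models, averaged predictions."""

    def __init__(self, model: MLRNNClassifier, models: list[MLRNNModel]):
        self.model = model
        self.models = models

    @property
    def n_trials(self) -> int:
        return len(self.models)

    def decision_scores(self, X) -> np.ndarray:
        return np.mean([m.decision_scores(X) for m in self.models], axis=0)

    def predict(self, X, threshold: float = 0.5):
        scores = self.decision_scores(X)
        return (scores >= threshold).astype(int), scores

    def predict_per_trial(self, X, threshold: float = 0.5) -> list[np.ndarray]:
        return [predict_mlrnn(m, X, threshold=threshold)[0] for m in self.models]

    def summary(self) -> str:
        ridges = [m.ridge for m in self.models]
        yhat, _ = self.predict(self.model.X)
        ba = _balanced_accuracy(self.model.y, yhat)
        lines = [
            "Multi-Layer Random Neural Network classifier",
            "=" * 44,
            f"structure:          {self.models[0].n_features} features -> "
            f"{self.models[0].n_inputs} inputs -> {self.models[0].n_hidden} hidden cells",
            f"trials averaged:    {self.n_trials}",
            f"selected ridge(s):  min {min(ridges):g}, max {max(ridges):g}",
            f"training BA:        {ba:.4f}",
        ]
        return "\n".join(lines)
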