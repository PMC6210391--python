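"""SMOTE minority oversampling for unbalanced assay training sets.

Synthetic minority samples are linear interpolations between a randomly
chosen minority point and one of its k nearest minority-class neighbours
(Euclidean distance over the full descriptor vector, binary fingerprint
columns included).  Interpolated values on fingerprint columns are kept
fractional, matching the behaviour of the usual SMOTE toolboxes.  Only
training partitions should ever be augmented; test partitions must stay
untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SMOTEConfig", "smote_augment"]


@dataclass
class SMOTEConfig:
    """k_neighbors: SMOTE's canonical 5; target: minority:majority ratio
    after augmentation (1.0 = fully balanced); seed drives all sampling."""

    k_neighbors: int = 5
    target: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0 < self.target <= 1.0):
            raise ValueError("target minority:majority ratio must be in (0, 1]")


def smote_augment(X, y, cfg: SMOTEConfig | None = None):
    """Oversample the minority class to the configured class ratio.

    Returns ``(X_aug, y_aug)`` with every original row first, in its
    original order, followed by the synthetic rows.  Each synthetic row is
    ``p + u * (n - p)`` for a random minority point ``p``, a random one of
    its ``k`` nearest minority neighbours ``n`` (ties broken by row index)
    and ``u ~ uniform[0, 1]``.  The number of synthetic rows is the
    smallest count reaching at least ``target * majority`` minority
    samples (rounding up).
    """
    cfg = cfg or SMOTEConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("y contains a single class; nothing to balance")
    if not set(classes) <= {0, 1}:
        raise ValueError("y must be binary (0/1)")
    minority = int(classes[np.argmin(counts)])
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    n_needed = int(math.ceil(cfg.target * n_maj)) - int(n_min)
    if n_needed <= 0:
        return X.copy(), y.copy()

    k = cfg.k_neighbors
    if k >= n_min:
        k = int(n_min) - 1
        warnings.warn(
            f"k_neighbors reduced to {k}: minority class has only {n_min} samples",
            stacklevel=2,
        )
    min_idx = np.flatnonzero(y == minority)
    Xm = X[min_idx]
    dist = cdist(Xm, Xm)
    np.fill_diagonal(dist, np.inf)
    # stable argsort: equal distances resolved by row index
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(cfg.seed)
    picks = rng.integers(0, n_min, size=n_needed)
    nb_slots = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    P = Xm[picks]
    N = Xm[neighbors[picks, nb_slots]]
    synthetic = P + u[:, None] * (N - P)

    X_aug = np.vstack([X, synthetic])
    y_aug = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_aug, y_aug
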