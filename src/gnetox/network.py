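"""G-Network / Random Neural Network core: representation, steady state, simulation.

A Random Neural Network (RNN) is the neural reading of a G-Network: ``n``
spiking cells hold non-negative integer potentials.  Cell ``i`` receives
exogenous excitatory spikes at Poisson rate ``Lambda[i]`` and inhibitory
spikes at rate ``lam[i]``; when its potential is positive it fires at rate
``r[i]``, sending an excitatory spike to cell ``j`` with probability
``w_plus[i, j] / r[i]`` or an inhibitory one with probability
``w_minus[i, j] / r[i]`` (the remainder leaves the network).  In steady
state the joint distribution of potentials has product form, and the
marginal probability ``q[i]`` that cell ``i`` is excited solves the
nonlinear fixed point

    q[i] = min(1, lam_plus[i] / (r[i] + lam_minus[i]))
    lam_plus[i]  = sum_j q[j] * w_plus[j, i]  + Lambda[i]
    lam_minus[i] = sum_j q[j] * w_minus[j, i] + lam[i]

which this module solves by damped successive substitution, and checks
against an independent discrete-event simulation of the Markov chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "RNNetwork",
    "SteadyState",
    "SimulationResult",
    "DegenerateNetworkError",
    "solve_fixed_point",
    "simulate_network",
]


class DegenerateNetworkError(ValueError):
    """A cell has zero total service/inhibition rate but positive excitatory drive."""


@dataclass
class RNNetwork:
    """Rates-and-weights description of a G-Network classifier.

    Parameters
    ----------
    w_plus, w_minus : (n, n) arrays
        Excitatory / inhibitory synaptic rates ``w+(i, j)``, ``w-(i, j)``
        (events per unit time), zero diagonal.
    Lambda : (n,) array
        Exogenous excitatory Poisson arrival rates.
    lam : (n,) array
        Exogenous inhibitory Poisson arrival rates.
    r : (n,) array
        Total firing rates; must satisfy ``r[i] >= sum_j w+(i,j) + w-(i,j)``
        (the slack is the departure/leak rate ``d[i]``).
    input_cells : tuple of int
        Cells whose ``Lambda`` entries carry injected descriptor values.
    output_cell : int or None
        Cell whose excitation probability is the classifier score.
    """

    w_plus: np.ndarray
    w_minus: np.ndarray
    Lambda: np.ndarray
    lam: np.ndarray
    r: np.ndarray
    input_cells: tuple = ()
    output_cell: int | None = None

    def __post_init__(self) -> None:
        self.w_plus = np.asarray(self.w_plus, dtype=float)
        self.w_minus = np.asarray(self.w_minus, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.input_cells = tuple(int(i) for i in self.input_cells)

    @property
    def n_cells(self) -> int:
        return self.r.shape[0]

    @property
    def leak(self) -> np.ndarray:
        """Departure rate d(i) = r(i) - row sum of synaptic rates."""
        return self.r - (self.w_plus.sum(axis=1) + self.w_minus.sum(axis=1))

    def validate(self) -> None:
        n = self.n_cells
        for name, arr, shape in (
            ("w_plus", self.w_plus, (n, n)),
            ("w_minus", self.w_minus, (n, n)),
            ("Lambda", self.Lambda, (n,)),
            ("lam", self.lam, (n,)),
            ("r", self.r, (n,)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative rates")
        if np.any(np.diag(self.w_plus) != 0) or np.any(np.diag(self.w_minus) != 0):
            raise ValueError("self-loops (w(i,i) != 0) are not allowed")
        if np.any(self.r <= 0):
            raise ValueError("all firing rates r(i) must be strictly positive")
        if np.any(self.leak < -1e-9 * np.maximum(self.r, 1.0)):
            raise ValueError("r(i) must be >= the row sum of synaptic rates")
        if self.output_cell is not None and not (0 <= self.output_cell < n):
            raise ValueError(f"output_cell {self.output_cell} out of range")
        for i in self.input_cells:
            if not (0 <= i < n):
                raise ValueError(f"input cell {i} out of range")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "w_plus": self.w_plus.tolist(),
            "w_minus": self.w_minus.tolist(),
            "Lambda": self.Lambda.tolist(),
            "lam": self.lam.tolist(),
            "r": self.r.tolist(),
            "input_cells": list(self.input_cells),
            "output_cell": self.output_cell,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RNNetwork":
        return cls(
            w_plus=np.array(d["w_plus"], dtype=float),
            w_minus=np.array(d["w_minus"], dtype=float),
            Lambda=np.array(d["Lambda"], dtype=float),
            lam=np.array(d["lam"], dtype=float),
            r=np.array(d["r"], dtype=float),
            input_cells=tuple(d.get("input_cells", ())),
            output_cell=d.get("output_cell"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "RNNetwork":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SteadyState:
    """Excitation-probability vector with convergence metadata."""

    q: np.ndarray
    residual: float
    iterations: int
    converged: bool
    stable: bool


@dataclass
class SimulationResult:
    """Empirical occupancy from the discrete-event simulation.

    ``occupancy[i]`` is the time-averaged fraction of time cell ``i``'s
    potential exceeded zero; ``stderr`` is the batch-means Monte-Carlo
    standard error of that average.
    """

    occupancy: np.ndarray
    stderr: np.ndarray
    n_events: int
    horizon: float


def fixed_point_batch(
    w_plus: np.ndarray,
    w_minus: np.ndarray,
    r: np.ndarray,
    Lambda: np.ndarray,
    lam: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    damping: float = 1.0,
    q0: np.ndarray | None = None,
):
    """Solve the product-form fixed point for a batch of exogenous drives.

    ``Lambda`` may be (n,) or (N, n); ``lam`` likewise.  Returns
    ``(Q, D, residual, iterations, stable)`` where ``Q`` are clamped
    excitation probabilities, ``D = r + lam_minus`` the per-cell
    denominators at the solution, and ``stable`` flags whether every
    pre-clamp ratio stayed strictly below 1.
    """
    Lambda = np.atleast_2d(np.asarray(Lambda, dtype=float))
    lam = np.asarray(lam, dtype=float)
    if lam.ndim == 1:
        lam = np.broadcast_to(lam, Lambda.shape)
    q = np.zeros_like(Lambda) if q0 is None else np.array(q0, dtype=float, copy=True)
    stable = True
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        num = q @ w_plus + Lambda
        den = r + q @ w_minus + lam
        bad = (den == 0) & (num > 0)
        if np.any(bad):
            raise DegenerateNetworkError(
                "cell with zero total rate r + lam_minus but positive excitatory drive"
            )
        ratio = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        q_new = np.minimum(ratio, 1.0)
        if np.any(ratio >= 1.0):
            stable = False
        q_new = (1.0 - damping) * q + damping * q_new
        residual = float(np.max(np.abs(q_new - q)))
        q = q_new
        if residual <= tol:
            break
    D = r + q @ w_minus + lam
    return q, D, residual, it, stable


def solve_fixed_point(
    net: RNNetwork,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    damping: float = 1.0,
) -> SteadyState:
    """Steady-state excitation probabilities by damped successive substitution.

    Iterates ``q <- min(1, lam_plus / (r + lam_minus))`` from ``q = 0``
    until the max absolute change drops below ``tol``.  Probabilities are
    clamped to [0, 1]; ``stable=False`` is recorded whenever any unclamped
    ratio reaches 1 (the product-form solution then does not exist).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    net.validate()
    q, _, residual, it, stable = fixed_point_batch(
        net.w_plus, net.w_minus, net.r, net.Lambda, net.lam,
        tol=tol, max_iter=max_iter, damping=damping,
    )
    return SteadyState(
        q=q[0],
        residual=residual,
        iterations=it,
        converged=residual <= tol,
        stable=stable,
    )


def simulate_network(
    net: RNNetwork,
    horizon: float = 1e5,
    seed: int = 0,
    warmup_frac: float = 0.05,
    n_batches: int = 50,
) -> SimulationResult:
    """Discrete-event simulation of the G-Network Markov chain.

    Exogenous excitatory/inhibitory arrivals are Poisson; an excited cell
    fires after an exponential holding time, losing one unit of potential
    and routing the spike by the ``w+/w-`` probabilities (excitatory spikes
    add one unit at the target, inhibitory ones subtract one, floored at
    zero).  Returns time-averaged occupancy (fraction of time each cell's
    potential exceeds 0) with batch-means standard errors; this is the
    independent oracle for the product-form fixed point.
    """
    net.validate()
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n = net.n_cells
    Lam = net.Lambda.copy()
    lam = net.lam.copy()
    r = net.r.copy()
    if Lam.sum() + lam.sum() + 0.0 == 0.0:
        # no exogenous events and (from the empty initial state) no firing
        raise ValueError("zero total event rate: network generates no events")

    rng = np.random.default_rng(seed)
    # flat per-cell routing tables: cumulative probabilities over
    # [excite j..., inhibit j..., depart]
    cum_route = np.cumsum(np.hstack([net.w_plus, net.w_minus]), axis=1)

    exo = np.concatenate([Lam, lam])
    total_exo = float(exo.sum())
    cum_exo = np.cumsum(exo)

    k = np.zeros(n, dtype=np.int64)
    warmup = warmup_frac * horizon
    batch_len = horizon / n_batches
    batch_occ = np.zeros((n_batches, n))

    t = -warmup  # negative time = warm-up, not accrued
    n_events = 0
    expovariate = rng.exponential
    uniform = rng.random
    while t < horizon:
        active = k > 0
        total_fire = float(r[active].sum())
        total = total_exo + total_fire
        if total <= 0.0:
            # absorbing empty state with no exogenous input: occupancy 0 onward
            break
        dt = expovariate(1.0 / total)
        t_next = min(t + dt, horizon)
        # accrue occupancy of `active` over [t, t_next), split across batches
        if t_next > 0.0 and np.any(active):
            lo = max(t, 0.0)
            b0 = int(lo // batch_len)
            b1 = min(int(t_next // batch_len), n_batches - 1)
            for b in range(b0, b1 + 1):
                seg = min(t_next, (b + 1) * batch_len) - max(lo, b * batch_len)
                if seg > 0:
                    batch_occ[b, active] += seg
        t = t + dt
        if t >= horizon:
            break
        n_events += 1
        u = uniform() * total
        if u < total_exo:
            idx = int(np.searchsorted(cum_exo, u, side="right"))
            if idx < n:
                k[idx] += 1
            else:
                j = idx - n
                if k[j] > 0:
                    k[j] -= 1
        else:
            # a firing event: pick the excited cell proportionally to r
            v = u - total_exo
            acc = 0.0
            i = -1
            for c in np.flatnonzero(active):
                acc += r[c]
                i = int(c)
                if v < acc:
                    break
            k[i] -= 1
            w = uniform() * r[i]
            row = cum_route[i]
            pos = int(np.searchsorted(row, w, side="right"))
            if pos < n:
                k[pos] += 1
            elif pos < 2 * n:
                j = pos - n
                if k[j] > 0:
                    k[j] -= 1
            # else: spike departs the network
    means = batch_occ / batch_len
    occupancy = means.mean(axis=0)
    stderr = means.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return SimulationResult(
        occupancy=occupancy, stderr=stderr, n_events=n_events, horizon=horizon
    )
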