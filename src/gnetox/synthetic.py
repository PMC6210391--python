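"""Synthetic ToxCast-like data: AC50 matrices with missingness and
descriptor tables with planted, recoverable signal.

The generator emulates the structure of a curated high-throughput
screening campaign: a compounds x assays AC50 matrix whose inactive cells
hold the 1,000,000 sentinel and whose untested cells are missing; a
descriptor block mixing continuous physico-chemical properties (uniform on
[0, 1]) with binary substructure fingerprints (Bernoulli, per-fingerprint
prevalence uniform on [0.05, 0.5]); and per-assay binary activity labels
drawn from a logistic model on a small random subset of informative
descriptors, with the intercept calibrated by bisection so the expected
active fraction of each assay matches its target (drawn uniform on
[0.05, 0.30] by default, mirroring the imbalance of real screening
panels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .curation import INACTIVE_SENTINEL, AssayMatrix, FeatureTable

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_assay_data",
    "generate_raw_matrix",
    "generate_bundle",
]


@dataclass
class SyntheticConfig:
    """Study-shaped defaults: 404 compounds x 37 assays, 74 continuous
    descriptors plus a fingerprint block, 5-30% active fractions."""

    n_compounds: int = 404
    n_assays: int = 37
    n_physchem: int = 74
    n_fingerprints: int = 160
    active_frac: float | tuple | None = None  # None -> per-assay U[0.05, 0.30]
    active_frac_range: tuple = (0.05, 0.30)
    n_informative: int = 10
    effect_size: float = 2.0
    missing_frac: float = 0.15
    ac50_log10_range: tuple = (-3.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_frac < 1):
            raise ValueError("missing_frac must be in [0, 1)")
        if self.n_informative > self.n_physchem + self.n_fingerprints:
            raise ValueError("n_informative exceeds the total feature count")
        lo, hi = self.active_frac_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("active_frac_range must satisfy 0 <= lo <= hi < 1")


@dataclass
class SyntheticBundle:
    """A raw generated dataset plus its planting record."""

    assay_matrix: AssayMatrix
    physchem: pd.DataFrame
    fingerprints: pd.DataFrame
    labels: pd.DataFrame            # planted per-assay activity (pre-masking truth)
    active_frac: np.ndarray         # per-assay target active fractions
    informative: dict               # assay -> (feature indices, coefficients)
    missing_mask: np.ndarray


def _target_fracs(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.active_frac is None:
        lo, hi = cfg.active_frac_range
        return rng.uniform(lo, hi, size=cfg.n_assays)
    return np.broadcast_to(np.asarray(cfg.active_frac, dtype=float),
                           (cfg.n_assays,)).copy()


def _calibrate_intercept(eta: np.ndarray, pi: float, tol: float = 1e-10) -> float:
    """Bisection on b so that mean(expit(eta + b)) == pi."""
    if pi <= 0.0:
        return -np.inf
    lo, hi = -60.0, 60.0
    f_lo = expit(eta + lo).mean() - pi
    f_hi = expit(eta + hi).mean() - pi
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError(
            f"intercept calibration failed for target active fraction {pi}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(eta + mid).mean() - pi > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _compound_ids(n: int) -> list:
    return [f"C{i:04d}" for i in range(n)]


def generate_assay_data(cfg: SyntheticConfig | None = None) -> tuple[FeatureTable, dict]:
    """Descriptor table + per-assay labels with planted logistic signal.

    Returns ``(FeatureTable, record)`` where ``record`` maps each assay to
    its informative feature indices, coefficients, intercept and target
    active fraction.  Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    ids = _compound_ids(cfg.n_compounds)
    pc = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(cfg.n_compounds, cfg.n_physchem)),
        index=ids, columns=[f"pc{j:03d}" for j in range(cfg.n_physchem)],
    )
    prevalence = rng.uniform(0.05, 0.5, size=cfg.n_fingerprints)
    fp = pd.DataFrame(
        (rng.uniform(size=(cfg.n_compounds, cfg.n_fingerprints)) < prevalence
         ).astype(int),
        index=ids, columns=[f"fp{j:03d}" for j in range(cfg.n_fingerprints)],
    )
    X = np.hstack([pc.to_numpy(), fp.to_numpy(dtype=float)])
    pis = _target_fracs(cfg, rng)
    n_feat = X.shape[1]
    labels = {}
    record = {"active_frac": pis, "assays": {}}
    for a in range(cfg.n_assays):
        name = f"assay{a:03d}"
        idx = rng.choice(n_feat, size=cfg.n_informative, replace=False)
        coef = rng.choice([-1.0, 1.0], size=cfg.n_informative) * cfg.effect_size
        eta = X[:, idx] @ coef
        b = _calibrate_intercept(eta, pis[a])
        p = expit(eta + b) if np.isfinite(b) else np.zeros(cfg.n_compounds)
        labels[name] = (rng.uniform(size=cfg.n_compounds) < p).astype(int)
        record["assays"][name] = {
            "informative": idx, "coef": coef, "intercept": b, "pi": pis[a],
        }
    labels = pd.DataFrame(labels, index=ids)
    table = FeatureTable(physchem=pc, fingerprints=fp, labels=labels)
    return table, record


def generate_raw_matrix(
    cfg: SyntheticConfig | None = None,
    labels: pd.DataFrame | None = None,
) -> tuple[AssayMatrix, dict]:
    """Raw AC50 matrix with missingness.

    Active cells draw log10-uniform AC50 values over
    ``cfg.ac50_log10_range``; inactive cells take the 1,000,000 sentinel;
    cells are masked missing independently with probability
    ``cfg.missing_frac``.  When ``labels`` is omitted, per-assay activity
    is Bernoulli with the configured active fractions.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    ids = _compound_ids(cfg.n_compounds)
    if labels is None:
        pis = _target_fracs(cfg, rng)
        lab = (rng.uniform(size=(cfg.n_compounds, cfg.n_assays)) < pis).astype(int)
        labels = pd.DataFrame(
            lab, index=ids, columns=[f"assay{a:03d}" for a in range(cfg.n_assays)]
        )
    lab = labels.to_numpy()
    lo, hi = cfg.ac50_log10_range
    ac50 = np.where(
        lab == 1,
        10.0 ** rng.uniform(lo, hi, size=lab.shape),
        INACTIVE_SENTINEL,
    )
    mask = rng.uniform(size=lab.shape) < cfg.missing_frac
    values = np.where(mask, np.nan, ac50)
    m = AssayMatrix(ac50=pd.DataFrame(values, index=labels.index,
                                      columns=labels.columns))
    return m, {"labels": labels, "missing_mask": mask, "ac50": ac50}


def generate_bundle(cfg: SyntheticConfig | None = None) -> SyntheticBundle:
    """Raw dataset with planted signal: descriptor tables, logistic labels
    and a masked AC50 matrix consistent with those labels."""
    cfg = cfg or SyntheticConfig()
    table, record = generate_assay_data(cfg)
    matrix, raw = generate_raw_matrix(cfg, labels=table.labels)
    return SyntheticBundle(
        assay_matrix=matrix,
        physchem=table.physchem,
        fingerprints=table.fingerprints,
        labels=table.labels,
        active_frac=record["active_frac"],
        informative=record["assays"],
        missing_mask=raw["missing_mask"],
    )
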