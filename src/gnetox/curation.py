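"""Assay-matrix curation: completion, AC50 binarisation, prevalence filters,
descriptor normalisation.

The raw input is a compounds x assays matrix of AC50 values (the compound
concentration giving half-maximal assay activity).  Inactive compounds
carry the sentinel value 1,000,000; untested combinations are missing.
Curation proceeds in a fixed, logged order:

1. extract a large complete sub-matrix (greedy deletion of the row/column
   with the most missing entries);
2. binarise activity (0 iff the AC50 equals the inactive sentinel);
3. drop assays with fewer than 5% active compounds;
4. drop fingerprints present in fewer than 5% of compounds;
5. min-max normalise the continuous physico-chemical descriptors to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INACTIVE_SENTINEL",
    "AssayMatrix",
    "FeatureTable",
    "MissingValueError",
    "binarize_activity",
    "extract_complete_submatrix",
    "filter_low_active_assays",
    "filter_rare_fingerprints",
    "normalize_physchem",
    "curate",
]

#: AC50 value recorded for compounds with no measurable activity.
INACTIVE_SENTINEL = 1_000_000.0
_SENTINEL_RTOL = 1e-9


class MissingValueError(ValueError):
    """AC50 values contain missing entries."""


@dataclass
class AssayMatrix:
    """Compounds x assays AC50 matrix; NaN marks missing entries."""

    ac50: pd.DataFrame

    def __post_init__(self):
        self.ac50 = self.ac50.astype(float)
        if (self.ac50.to_numpy() <= 0).any():
            raise ValueError("AC50 values must be positive (or missing)")

    @property
    def compounds(self) -> list:
        return list(self.ac50.index)

    @property
    def assays(self) -> list:
        return list(self.ac50.columns)

    @property
    def n_missing(self) -> int:
        return int(self.ac50.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0


@dataclass
class FeatureTable:
    """Curated modelling table: normalised physchem block, binary
    fingerprint block and per-assay binary labels, aligned on compounds."""

    physchem: pd.DataFrame
    fingerprints: pd.DataFrame
    labels: pd.DataFrame
    normalization: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        idx = self.physchem.index
        for name, df in (("fingerprints", self.fingerprints), ("labels", self.labels)):
            if not df.index.equals(idx):
                raise ValueError(f"{name} index does not match physchem index")
        pc = self.physchem.to_numpy(dtype=float)
        if pc.size and (pc.min() < -1e-12 or pc.max() > 1 + 1e-12):
            raise ValueError("physchem block must lie in [0, 1]")
        for name, df in (("fingerprints", self.fingerprints), ("labels", self.labels)):
            vals = df.to_numpy()
            if vals.size and not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} must be binary 0/1")

    @property
    def compounds(self) -> list:
        return list(self.physchem.index)

    def features(self) -> np.ndarray:
        """Physchem + fingerprint blocks as one float matrix in [0, 1]."""
        return np.hstack([
            self.physchem.to_numpy(dtype=float),
            self.fingerprints.to_numpy(dtype=float),
        ])

    @property
    def feature_names(self) -> list:
        return list(self.physchem.columns) + list(self.fingerprints.columns)


def is_inactive(values) -> np.ndarray:
    """Tolerant comparison with the 1,000,000 inactive sentinel (values
    survive CSV round-trips)."""
    values = np.asarray(values, dtype=float)
    return values >= INACTIVE_SENTINEL * (1.0 - _SENTINEL_RTOL)


def binarize_activity(ac50):
    """Binary activity labels: 0 iff AC50 is the inactive sentinel, else 1.

    Missing values are rejected; run :func:`extract_complete_submatrix`
    first.
    """
    if isinstance(ac50, pd.DataFrame):
        if ac50.isna().to_numpy().any():
            raise MissingValueError(
                "AC50 matrix has missing entries; extract a complete "
                "sub-matrix with extract_complete_submatrix() first"
            )
        return pd.DataFrame(
            (~is_inactive(ac50.to_numpy())).astype(int),
            index=ac50.index, columns=ac50.columns,
        )
    values = np.asarray(ac50, dtype=float)
    if np.isnan(values).any():
        raise MissingValueError(
            "AC50 values contain missing entries; extract a complete "
            "sub-matrix with extract_complete_submatrix() first"
        )
    return (~is_inactive(values)).astype(int)


def extract_complete_submatrix(m: AssayMatrix):
    """Greedy large complete sub-matrix.

    While missing entries remain, delete the row or column with the
    largest missing *fraction*; ties resolved by larger absolute missing
    count, then column before row, then lowest positional index.  Returns
    the complete :class:`AssayMatrix` and the deletion log.
    """
    df = m.ac50.copy()
    log: list[tuple[str, object]] = []
    while df.size and df.isna().to_numpy().any():
        na = df.isna()
        nrows, ncols = df.shape
        col_cnt = na.sum(axis=0).to_numpy()
        row_cnt = na.sum(axis=1).to_numpy()
        # key: (-fraction, -count, col_before_row, position); pick min
        best = None
        for j in range(ncols):
            key = (-col_cnt[j] / nrows, -col_cnt[j], 0, j)
            if best is None or key < best[0]:
                best = (key, "column", j)
        for i in range(nrows):
            key = (-row_cnt[i] / ncols, -row_cnt[i], 1, i)
            if key < best[0]:
                best = (key, "row", i)
        _, kind, pos = best
        if kind == "column":
            log.append(("column", df.columns[pos]))
            df = df.drop(columns=df.columns[pos])
        else:
            log.append(("row", df.index[pos]))
            df = df.drop(index=df.index[pos])
    if df.size == 0:
        warnings.warn("complete sub-matrix extraction removed everything",
                      stacklevel=2)
    return AssayMatrix(ac50=df), log


def filter_low_active_assays(labels: pd.DataFrame, min_frac: float = 0.05) -> list:
    """Assays retained iff their active fraction is >= ``min_frac``
    (strictly-below-threshold assays are removed)."""
    if labels.size == 0:
        raise ValueError("label matrix is empty")
    frac = labels.to_numpy().mean(axis=0)
    return [a for a, f in zip(labels.columns, frac) if f >= min_frac]


def filter_rare_fingerprints(fp: pd.DataFrame, min_frac: float = 0.05) -> list:
    """Fingerprints retained iff present in >= ``min_frac`` of compounds."""
    if fp.size == 0:
        raise ValueError("fingerprint matrix is empty")
    prev = fp.to_numpy().mean(axis=0)
    return [c for c, p in zip(fp.columns, prev) if p >= min_frac]


def normalize_physchem(X: pd.DataFrame, stats: dict | None = None):
    """Per-column min-max scaling to [0, 1]; constant columns map to 0.

    When ``stats`` is given the stored (min, max) pairs are applied
    (train-only fitting); otherwise they are fitted from ``X`` itself
    (whole-dataset fitting, the default in :func:`curate`).  Returns the
    scaled frame and the statistics for reuse.
    """
    arr = X.to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value in physchem column {X.columns[j]!r} "
            f"(compound {X.index[i]!r})"
        )
    if stats is None:
        stats = {c: (float(X[c].min()), float(X[c].max())) for c in X.columns}
    out = {}
    for c in X.columns:
        lo, hi = stats[c]
        col = X[c].to_numpy(dtype=float)
        if hi > lo:
            out[c] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[c] = np.zeros_like(col)
    return pd.DataFrame(out, index=X.index), stats


def curate(
    ac50: AssayMatrix,
    physchem: pd.DataFrame,
    fingerprints: pd.DataFrame,
    min_active_frac: float = 0.05,
    min_fingerprint_frac: float = 0.05,
    normalization_stats: dict | None = None,
):
    """Full curation pipeline; returns ``(FeatureTable, log)``.

    Fixed order: complete sub-matrix -> binarise -> assay prevalence
    filter -> fingerprint prevalence filter -> physchem normalisation.
    Descriptor tables are restricted to the surviving compounds.
    """
    log: list[str] = []
    log.append(f"input: {len(ac50.compounds)} compounds x {len(ac50.assays)} assays, "
               f"{ac50.n_missing} missing")
    complete, deletions = extract_complete_submatrix(ac50)
    log.append(f"complete sub-matrix: {len(complete.compounds)} compounds x "
               f"{len(complete.assays)} assays ({len(deletions)} deletions)")
    labels = binarize_activity(complete.ac50)
    kept_assays = filter_low_active_assays(labels, min_frac=min_active_frac)
    labels = labels[kept_assays]
    log.append(f"assay filter (<{min_active_frac:.0%} active removed): "
               f"{len(kept_assays)} assays kept")
    compounds = complete.compounds
    missing = [c for c in compounds
               if c not in physchem.index or c not in fingerprints.index]
    if missing:
        raise ValueError(f"descriptor tables lack compounds: {missing[:5]}")
    fp = fingerprints.loc[compounds]
    kept_fp = filter_rare_fingerprints(fp, min_frac=min_fingerprint_frac)
    fp = fp[kept_fp]
    log.append(f"fingerprint filter (<{min_fingerprint_frac:.0%} prevalence removed): "
               f"{len(kept_fp)} fingerprints kept")
    pc, stats = normalize_physchem(physchem.loc[compounds],
                                   stats=normalization_stats)
    log.append(f"physchem normalised to [0, 1]: {pc.shape[1]} descriptors")
    table = FeatureTable(physchem=pc, fingerprints=fp.astype(int),
                         labels=labels.astype(int), normalization=stats)
    return table, log
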