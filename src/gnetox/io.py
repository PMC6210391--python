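"""CSV dialects, run configuration and logging helpers.

All tables share one dialect: a header row with descriptor/assay names,
the first column holding compound identifiers.  In AC50 tables an empty
cell means missing; descriptor and label tables must be fully populated.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curation import AssayMatrix

__all__ = [
    "read_feature_csv",
    "write_feature_csv",
    "read_ac50_csv",
    "write_ac50_csv",
    "RunConfig",
    "setup_logging",
]

logger = logging.getLogger("gnetox")


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate compound ID {dup!r} in {path}")
    return df


def _to_float(df: pd.DataFrame, path, allow_missing: bool) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        raw = df[col]
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = vals.isna() & (raw.str.strip() != "")
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(
                f"malformed cell in {path}: row {row!r}, column {col!r} "
                f"= {raw[bad].iloc[0]!r}"
            )
        if not allow_missing and vals.isna().any():
            row = vals.index[vals.isna()][0]
            raise ValueError(f"missing value in {path}: row {row!r}, column {col!r}")
        out[col] = vals
    return pd.DataFrame(out, index=df.index)


def read_feature_csv(path, kind: str = "continuous") -> pd.DataFrame:
    """Read a descriptor or label table.

    ``kind='fingerprint'`` (or ``'label'``) additionally validates every
    cell as 0/1, naming the offending cell otherwise.
    """
    df = _to_float(_read_table(path), path, allow_missing=False)
    if kind in ("fingerprint", "label"):
        arr = df.to_numpy()
        bad = ~np.isin(arr, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary {kind} cell in {path}: row {df.index[i]!r}, "
                f"column {df.columns[j]!r} = {arr[i, j]!r}"
            )
        return df.astype(int)
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="compound")


def read_ac50_csv(path) -> AssayMatrix:
    """Read an AC50 matrix; empty cells become missing entries."""
    return AssayMatrix(ac50=_to_float(_read_table(path), path, allow_missing=True))


def write_ac50_csv(m: AssayMatrix, path) -> None:
    m.ac50.to_csv(path, index_label="compound", na_rep="")


@dataclass
class RunConfig:
    """Serializable description of a benchmark run."""

    data_dir: str = "."
    out_dir: str = "results"
    methods: tuple = ("rnn", "mlrnn", "xgboost")
    repeats: int = 50
    test_frac: float = 0.25
    augment: bool = True
    seed: int = 0
    smote_k: int = 5
    rnn: dict = field(default_factory=dict)
    mlrnn: dict = field(default_factory=dict)
    xgboost: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["methods"] = list(d["methods"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["methods"] = tuple(d.get("methods", ()))
        return cls(**d)


def setup_logging(log_path=None, seed=None, config=None) -> None:
    """Plain-text run log recording configuration, seed and versions."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_path is not None:
        handlers.append(logging.FileHandler(log_path))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
    import gnetox

    logger.info("gnetox %s | numpy %s | pandas %s",
                gnetox.__version__, np.__version__, pd.__version__)
    if seed is not None:
        logger.info("seed: %s", seed)
    if config is not None:
        logger.info("config: %s", config)
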