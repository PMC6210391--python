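"""Repeated random-split benchmark with Sensitivity/Specificity/Balanced
Accuracy, paired unbalanced vs SMOTE-augmented conditions.

For each assay the compound set D is split R times (50 by default) into a
training partition DT and its complement Dt; each classifier is trained on
DT (optionally SMOTE-balanced — Dt is never touched) and scored on Dt.
Reported metrics per test split:

    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    BA          = (Sensitivity + Specificity) / 2

An empty denominator yields NaN, which is excluded from aggregation (and
counted), never silently zeroed.  The same SplitSet is used for both
conditions, so the comparison is paired on byte-identical test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit

from .augment import SMOTEConfig, smote_augment
from .curation import FeatureTable
from .learning import predict_rnn, train_rnn
from .mlrnn import train_mlrnn, predict_mlrnn

__all__ = [
    "SplitSet",
    "MetricsRow",
    "BenchmarkConfig",
    "make_splits",
    "compute_metrics",
    "run_benchmark",
    "aggregate",
    "plot_summary",
]

CONDITIONS = ("unbalanced", "augmented")


@dataclass
class SplitSet:
    """R seeded random (train, test) partitions of range(n)."""

    splits: list
    n: int
    test_frac: float
    seed: int
    stratified: bool

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def make_splits(
    n: int,
    R: int = 50,
    test_frac: float = 0.25,
    seed: int = 0,
    stratify_on=None,
) -> SplitSet:
    """R independent random train/test partitions, reproducible from seed.

    With ``stratify_on`` (per-compound labels) each partition keeps both
    classes on both sides; infeasible stratification raises with the class
    counts.
    """
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if stratify_on is not None:
        y = np.asarray(stratify_on).ravel()
        counts = np.bincount(y.astype(int), minlength=2)
        if counts.min() < 2:
            raise ValueError(
                f"stratification infeasible: class counts {counts.tolist()} "
                "(need >= 2 per class)"
            )
        splitter = StratifiedShuffleSplit(
            n_splits=R, test_size=test_frac, random_state=seed
        )
        splits = [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros(n), y)]
    else:
        splitter = ShuffleSplit(n_splits=R, test_size=test_frac, random_state=seed)
        splits = [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros(n))]
    return SplitSet(splits=splits, n=n, test_frac=test_frac, seed=seed,
                    stratified=stratify_on is not None)


@dataclass
class MetricsRow:
    """Confusion counts and derived metrics for one evaluation."""

    tp: float
    fp: float
    tn: float
    fn: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float


def compute_metrics(y_true, y_pred) -> MetricsRow:
    """Exhaustive confusion tally; NaN marks an undefined metric (empty
    denominator), which is propagated rather than zeroed."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    ba = (sens + spec) / 2.0
    return MetricsRow(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                      specificity=spec, balanced_accuracy=ba)


@dataclass
class BenchmarkConfig:
    """Per-method settings for the benchmark harness.

    ``rnn``/``mlrnn``/``xgboost`` are keyword dictionaries passed to the
    respective trainers; ``smote`` configures augmentation.  The defaults
    keep the recurrent RNN small enough for repeated fits on a few hundred
    compounds.
    """

    rnn: dict = field(default_factory=lambda: {
        "n_hidden": 4, "lr": 2.0, "epochs": 25,
    })
    mlrnn: dict = field(default_factory=lambda: {
        "n_trials": 20,
    })
    xgboost: dict = field(default_factory=dict)
    smote: dict = field(default_factory=lambda: {"k_neighbors": 5, "target": 1.0})
    threshold: float = 0.5


def _derive_seed(master: int, *key) -> int:
    """Counter-based per-cell seed, reproducible across platforms."""
    return int(np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
               .generate_state(1)[0] % (2**31))


def _fit_predict(method, Xtr, ytr, Xte, seed, cfg: BenchmarkConfig):
    """Train one method and return one or more test predictions (one per
    trial; metrics of multiple trials are averaged by the caller)."""
    if method == "rnn":
        trace = train_rnn(Xtr, ytr, seed=seed, **cfg.rnn)
        yhat, _ = predict_rnn(trace.network, Xte, threshold=cfg.threshold)
        return [yhat]
    if method == "mlrnn":
        opts = dict(cfg.mlrnn)
        n_trials = opts.pop("n_trials", 20)
        seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
        preds = []
        for s in seeds:
            model = train_mlrnn(Xtr, ytr, seed=int(s), **opts)
            preds.append(predict_mlrnn(model, Xte, threshold=cfg.threshold)[0])
        return preds
    if method == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "the 'xgboost' method requires the xgboost library"
            ) from exc
        clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **cfg.xgboost)
        clf.fit(Xtr, ytr)
        return [clf.predict(Xte).astype(int)]
    if method == "majority":
        maj = int(np.bincount(ytr.astype(int)).argmax())
        return [np.full(Xte.shape[0], maj, dtype=int)]
    raise ValueError(f"unknown method {method!r}; no adapter registered")


def run_benchmark(
    table: FeatureTable,
    methods=("rnn", "mlrnn", "xgboost"),
    splits: SplitSet | dict | None = None,
    conditions=CONDITIONS,
    config: BenchmarkConfig | None = None,
    R: int = 50,
    test_frac: float = 0.25,
    seed: int = 0,
    assays=None,
) -> pd.DataFrame:
    """Assay x repeat x method x condition benchmark; returns a tidy frame.

    ``splits`` may be a precomputed ``{assay: SplitSet}`` mapping;
    otherwise stratified splits are drawn per assay from ``seed``.  In the
    "augmented" condition only the training partition is SMOTE-balanced.
    A training failure is recorded as a failed cell (NaN metrics, error
    message) and the run continues.
    """
    if not methods:
        raise ValueError("methods must be non-empty")
    known = {"rnn", "mlrnn", "xgboost", "majority"}
    unknown = [m for m in methods if m not in known]
    if unknown:
        raise ValueError(
            f"unknown method {unknown[0]!r}; no adapter registered "
            f"(available: {sorted(known)})"
        )
    config = config or BenchmarkConfig()
    X = table.features()
    assays = list(assays) if assays is not None else list(table.labels.columns)
    rows = []
    for ai, assay in enumerate(assays):
        y = table.labels[assay].to_numpy()
        if isinstance(splits, dict):
            assay_splits = splits[assay]
        elif isinstance(splits, SplitSet):
            assay_splits = splits
        else:
            try:
                assay_splits = make_splits(
                    len(y), R=R, test_frac=test_frac,
                    seed=_derive_seed(seed, ai), stratify_on=y,
                )
            except ValueError as exc:
                raise ValueError(f"assay {assay!r}: {exc}") from exc
        for rep, (tr, te) in enumerate(assay_splits):
            Xte, yte = X[te], y[te]
            for condition in conditions:
                if condition == "augmented":
                    Xtr, ytr = smote_augment(
                        X[tr], y[tr],
                        SMOTEConfig(seed=_derive_seed(seed, ai, rep, 9),
                                    **config.smote),
                    )
                else:
                    Xtr, ytr = X[tr], y[tr]
                for mi, method in enumerate(methods):
                    cell_seed = _derive_seed(seed, ai, rep, mi)
                    base = {"assay": assay, "repeat": rep, "method": method,
                            "condition": condition, "n_test": len(te)}
                    try:
                        preds = _fit_predict(method, Xtr, ytr, Xte,
                                             cell_seed, config)
                        metrics = [compute_metrics(yte, p) for p in preds]
                        agg = {k: float(np.mean([getattr(m, k) for m in metrics]))
                               for k in ("tp", "fp", "tn", "fn", "sensitivity",
                                         "specificity", "balanced_accuracy")}
                        rows.append({**base, **agg, "error": ""})
                    except (ValueError, RuntimeError) as exc:
                        rows.append({**base, "tp": np.nan, "fp": np.nan,
                                     "tn": np.nan, "fn": np.nan,
                                     "sensitivity": np.nan, "specificity": np.nan,
                                     "balanced_accuracy": np.nan,
                                     "error": str(exc)})
    return pd.DataFrame(rows)


def aggregate(results: pd.DataFrame, by=("assay", "method", "condition")) -> pd.DataFrame:
    """Unweighted means and standard deviations over repeats; failed or
    undefined cells are excluded and counted in ``n_excluded``."""
    metrics = ["sensitivity", "specificity", "balanced_accuracy"]
    out = []
    for key, grp in results.groupby(list(by)):
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n_repeats"] = len(grp)
        for m in metrics:
            vals = grp[m]
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_std"] = float(vals.std(ddof=1)) if vals.notna().sum() > 1 else np.nan
        row["n_excluded"] = int(grp[metrics].isna().any(axis=1).sum())
        out.append(row)
    return pd.DataFrame(out)


def plot_summary(agg: pd.DataFrame, path=None, metric: str = "balanced_accuracy_mean"):
    """Per-assay summary figure: one line per (method, condition)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    assays = sorted(agg["assay"].unique())
    xs = np.arange(len(assays))
    for (method, condition), grp in agg.groupby(["method", "condition"]):
        series = grp.set_index("assay").reindex(assays)[metric]
        ax.plot(xs, series.to_numpy(), marker="o", label=f"{method} ({condition})")
    ax.set_xticks(xs)
    ax.set_xticklabels(assays, rotation=90, fontsize=7)
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_xlabel("assay")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
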