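"""Experiment protocol: stratified splits, accuracy, repeated runs, comparisons.

The evaluation follows the standard vigilance-classification protocol: the
labeled epochs are split 7:3 into train and test (stratified so both states
appear on each side), a model is trained and scored by recognition accuracy

    Acc = (TP + TN) / (TP + TN + FP + FN)      (fatigue = positive)

and the whole cycle is repeated (default 10 times) with derived seeds
``base_seed + run_index``; reports carry per-run values, the mean, and the
size of the training set actually handed to the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import ConfigError, DataError
from .fsvm import KernelSpec, LabeledDataset, TrainedModel, train_fsvm, train_svm


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with fatigue (label 1) as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DataError("prediction/label length mismatch")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Recognition accuracy (TP + TN) / total."""
    if c.total == 0:
        raise DataError("no evaluated samples")
    return (c.TP + c.TN) / c.total


def split_dataset(
    ds: LabeledDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random train/test split preserving class proportions."""
    if not (0.0 < train_fraction < 1.0):
        raise ConfigError("train_fraction must be in (0, 1)")
    if ds.l_pos < 2 or ds.l_neg < 2:
        raise DataError("each class needs at least 2 members to split")
    idx = np.arange(len(ds))
    tr, te = train_test_split(
        idx, train_size=train_fraction, stratify=ds.y, random_state=seed
    )
    tr, te = np.sort(tr), np.sort(te)
    return (
        LabeledDataset(X=ds.X[tr], y=ds.y[tr]),
        LabeledDataset(X=ds.X[te], y=ds.y[te]),
    )


@dataclass(frozen=True)
class ModelSpec:
    """What to train in a repeated evaluation: plain SVM or FSVM at ratio r."""

    kind: str = "fsvm"  # "svm" | "fsvm"
    kernel: KernelSpec = KernelSpec()
    r: float = 0.5
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "fsvm"):
            raise ConfigError(f"unknown model kind {self.kind!r}")

    def train(self, ds: LabeledDataset) -> TrainedModel:
        if self.kind == "svm":
            return train_svm(ds, self.kernel, self.C)
        return train_fsvm(ds, self.kernel, self.r, self.C)


@dataclass
class ExperimentReport:
    """Per-run accuracies plus provenance for one evaluated configuration."""

    name: str
    accuracies: list[float]
    solver_sizes: list[int]
    seeds: list[int]
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mean_accuracy": self.mean_accuracy,
            "accuracies": self.accuracies,
            "solver_sizes": self.solver_sizes,
            "seeds": self.seeds,
            "config": self.config,
        }


def _run_once(
    ds: LabeledDataset,
    spec: ModelSpec | Callable,
    seed: int,
    train_fraction: float,
) -> tuple[float, int]:
    train, test = split_dataset(ds, train_fraction, seed)
    if isinstance(spec, ModelSpec):
        model = spec.train(train)
        n_solver = (
            len(train) if model.selected_indices is None else model.n_selected
        )
        y_pred = model.predict(test.X)
    else:  # duck-typed estimator factory: spec(seed) -> obj with fit/predict
        est = spec(seed)
        est.fit(train.X, train.y)
        n_solver = len(train)
        y_pred = est.predict(test.X)
    return accuracy(confusion(test.y, y_pred)), int(n_solver)


def repeated_eval(
    ds: LabeledDataset,
    spec: ModelSpec | Callable = ModelSpec(),
    reps: int = 10,
    base_seed: int = 0,
    train_fraction: float = 0.7,
    name: str | None = None,
) -> ExperimentReport:
    """``reps`` independent split → train → test cycles with derived seeds."""
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    seeds = [base_seed + i for i in range(reps)]
    accs, sizes = [], []
    for run, s in enumerate(seeds):
        try:
            a, n = _run_once(ds, spec, s, train_fraction)
        except Exception as e:
            raise type(e)(f"run {run} (seed {s}): {e}") from e
        accs.append(a)
        sizes.append(n)
    cfg = (
        {
            "kind": spec.kind,
            "kernel": spec.kernel.kind,
            "gamma": spec.kernel.gamma,
            "r": spec.r,
            "C": spec.C,
        }
        if isinstance(spec, ModelSpec)
        else {"kind": "custom"}
    )
    cfg.update({"reps": reps, "train_fraction": train_fraction})
    return ExperimentReport(
        name=name or (cfg["kind"] if isinstance(spec, ModelSpec) else "custom"),
        accuracies=accs,
        solver_sizes=sizes,
        seeds=seeds,
        config=cfg,
    )


def compare_models(
    ds: LabeledDataset,
    r_grid: list[float],
    kernel: KernelSpec = KernelSpec(),
    C: float = 1.0,
    reps: int = 10,
    base_seed: int = 0,
) -> dict:
    """FSVM at each ratio r against the plain-SVM baseline on identical splits.

    Returns a machine-readable report: the baseline plus one row per r with
    mean accuracy, per-run accuracies and the solver-input sizes.
    """
    for r in r_grid:
        if not (0.0 < r <= 1.0):
            raise ConfigError(f"r values must be in (0, 1], got {r}")
    baseline = repeated_eval(
        ds, ModelSpec(kind="svm", kernel=kernel, C=C), reps, base_seed, name="svm"
    )
    rows = []
    for r in r_grid:
        rep = repeated_eval(
            ds,
            ModelSpec(kind="fsvm", kernel=kernel, r=r, C=C),
            reps,
            base_seed,
            name=f"fsvm(r={r})",
        )
        rows.append(rep.to_dict() | {"r": r})
    return {"baseline": baseline.to_dict(), "fsvm": rows}


def render_comparison(report: dict) -> str:
    """Plain-text table of a :func:`compare_models` report."""
    lines = [f"{'model':<14} {'r':>5} {'mean acc':>9} {'solver size':>12}"]
    b = report["baseline"]
    lines.append(
        f"{'SVM':<14} {'-':>5} {b['mean_accuracy']:>9.4f} "
        f"{int(np.mean(b['solver_sizes'])):>12d}"
    )
    for row in report["fsvm"]:
        lines.append(
            f"{'FSVM':<14} {row['r']:>5.2f} {row['mean_accuracy']:>9.4f} "
            f"{int(np.mean(row['solver_sizes'])):>12d}"
        )
    return "\n".join(lines)
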