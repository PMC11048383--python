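"""Evaluation metrics and the learning-curve experiment harness.

Regression is scored by MAE = (1/N) Σ|ŷ_i − y_i| along with MSE, RMSE and
R² = 1 − SS_res/SS_tot; classification by accuracy (correct/total) with
precision, recall and F1 for the positive class (male by default).  The
learning-curve experiment trains every model with identical hyperparameters
on nested stages of training-set size — for the 1157-subject design the
published sweep {57, 115, 231, 462, 694, 925} — and scores each against one
fixed held-out test partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import baselines as _baselines
from .preprocess import fit_preprocess, split, subsample_train
from .vqc import VQCClassifier, VQCConfig, VQCRegressor

__all__ = [
    "RegressionMetrics",
    "ClassificationMetrics",
    "regression_metrics",
    "classification_metrics",
    "make_estimator",
    "run_learning_curve",
    "DEFAULT_SIZE_FRACTIONS",
]

DEFAULT_SIZE_FRACTIONS = (0.05, 0.10, 0.20, 0.40, 0.60, 0.80)


@dataclass(frozen=True)
class RegressionMetrics:
    mae: float
    mse: float
    rmse: float
    r2: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def regression_metrics(y, y_pred) -> RegressionMetrics:
    """MAE, MSE, RMSE and R² of predictions against true values."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y and y_pred must be equal-length 1-d arrays with at least 2 entries")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_pred))):
        raise ValueError("metrics require finite inputs")
    err = y_pred - y
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero-variance targets: R^2 is undefined (NaN)", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    return RegressionMetrics(mae=mae, mse=mse, rmse=float(np.sqrt(mse)), r2=r2, n=y.size)


def classification_metrics(y, y_pred, positive_label="M") -> ClassificationMetrics:
    """Accuracy plus positive-class precision, recall and F1.

    Zero denominators (no predicted or no true positives) yield 0 with a
    warning rather than an exception, so model sweeps never abort.
    """
    y = np.asarray(y)
    y_pred = np.asarray(y_pred)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError("y and y_pred must be equal-length 1-d arrays")
    labels = set(np.unique(y)) | set(np.unique(y_pred))
    if len(labels - {positive_label}) > 1:
        raise ValueError(f"expected binary labels, got {sorted(map(str, labels))}")
    pos_true = y == positive_label
    pos_pred = y_pred == positive_label
    tp = int(np.sum(pos_true & pos_pred))
    fp = int(np.sum(~pos_true & pos_pred))
    tn = int(np.sum(~pos_true & ~pos_pred))
    fn = int(np.sum(pos_true & ~pos_pred))
    accuracy = (tp + tn) / y.size

    def _safe_div(num, den, what):
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return ClassificationMetrics(accuracy=accuracy, precision=precision, recall=recall,
                                 f1=f1, tp=tp, fp=fp, tn=tn, fn=fn, n=int(y.size))


def make_estimator(name: str, task: str, seed: int, k: int, vqc_config: VQCConfig | None = None):
    """Uniform factory: 'VQC' or any baseline name, sharing one code path."""
    if name.upper() == "VQC":
        cls = VQCRegressor if task == "regression" else VQCClassifier
        if vqc_config is not None:
            return cls(vqc_config, n_qubits=k, seed=seed, task=task)
        return cls(n_qubits=k, seed=seed)
    return _baselines.make_baseline(name, task, seed=seed)


def _metrics_for(task: str, y, y_pred):
    if task == "regression":
        return regression_metrics(y, y_pred).as_dict()
    return classification_metrics(y, y_pred).as_dict()


def run_learning_curve(
    cohort: pd.DataFrame,
    sizes=DEFAULT_SIZE_FRACTIONS,
    models=("LR",),
    task: str = "regression",
    seed: int = 0,
    k: int = 17,
    vqc_config: VQCConfig | None = None,
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Train each model at each training size; score train and fixed test set.

    ``sizes`` are fractions of the cohort size in (0, 0.8]; the training
    subsample holds floor(fraction·N) subjects.  Preprocessing (min-max +
    k-component PCA) is refitted on each training subsample, so no test
    information leaks into the representation.  A failing (model, size) cell
    is recorded as an error row instead of aborting the sweep.

    Returns a tidy DataFrame with one row per (repeat, size, model,
    partition) carrying the task's metrics.
    """
    target_col = "age" if task == "regression" else "sex"
    sp = split(cohort, seed=seed)
    indexed = cohort.set_index("subject_id", drop=False)
    test_tab = indexed.loc[list(sp.test_ids)]
    y_test = test_tab[target_col].to_numpy()

    rows: list[dict] = []
    for rep in range(n_repeats):
        for frac in sizes:
            ids = subsample_train(sp, frac, seed=seed + 1000 * rep + 1)
            train_tab = indexed.loc[list(ids)]
            y_train = train_tab[target_col].to_numpy()
            pre = fit_preprocess(train_tab, k=k)
            X_train = pre.transform(train_tab)
            X_test = pre.transform(test_tab)
            for name in models:
                base = dict(model=name, train_size=len(ids), fraction=frac,
                            repeat=rep, seed=seed, error="")
                try:
                    est = make_estimator(name, task, seed=seed + rep, k=k, vqc_config=vqc_config)
                    est.fit(X_train, y_train)
                    for part, Xp, yp in (("train", X_train, y_train), ("test", X_test, y_test)):
                        rows.append({**base, "partition": part,
                                     **_metrics_for(task, yp, est.predict(Xp))})
                except Exception as exc:  # error row, sweep continues
                    rows.append({**base, "partition": "error", "error": f"{type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)


def plot_learning_curve(result: pd.DataFrame, metric: str, ax=None):
    """Metric vs training size, one line per model (train and test panels share x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = result[result["partition"] != "error"]
    for (model, part), grp in ok.groupby(["model", "partition"]):
        grp = grp.sort_values("train_size")
        ax.plot(grp["train_size"], grp[metric], marker="o",
                linestyle="-" if part == "test" else "--", label=f"{model} ({part})")
    ax.set_xlabel("training samples")
    ax.set_ylabel(metric)
    ax.legend(fontsize=7)
    return ax
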