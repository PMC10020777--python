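"""Wrapper feature selection with a Gaussian Naive Bayes fitness.

The pipeline reads a delimited table with a header row and a label
column, imputes missing values, fixes a single stratified train/test
split for the whole run, and scores candidate feature subsets by the
test-set accuracy of a Naive Bayes classifier trained on the selected
columns. The binary optimizer drives the subset search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB

from .binary import BinaryRunResult, TransferConfig, run_brpo
from .core import RPOConfig

__all__ = [
    "Dataset",
    "SplitConfig",
    "TrainTestSplit",
    "MetricsReport",
    "load_dataset",
    "preprocess",
    "make_split",
    "nb_fitness",
    "evaluate_metrics",
    "execution_time_metric",
    "select_features",
    "run_fs_experiment",
]

NEGATIVE, POSITIVE = "negative", "positive"


@dataclass
class Dataset:
    """A feature matrix with binary labels.

    ``labels`` hold the canonical tokens ``"negative"``/``"positive"``.
    ``informative_mask`` is ground truth available for synthetic data
    only.
    """

    features: pd.DataFrame
    labels: np.ndarray
    feature_names: list[str]
    informative_mask: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def validate(self) -> None:
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("labels must contain both classes")


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.3
    seed: int = 0


@dataclass
class TrainTestSplit:
    x_train: np.ndarray
    x_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray


@dataclass
class MetricsReport:
    accuracy: float  # percent, [0, 100]
    micro_precision: float
    micro_recall: float
    macro_precision: float
    macro_recall: float
    f_measure: float
    execution_time_metric: int = 0
    zero_predicted_classes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "f_measure": self.f_measure,
            "execution_time_metric": self.execution_time_metric,
            "zero_predicted_classes": self.zero_predicted_classes,
        }


def load_dataset(
    path,
    *,
    label_col: str,
    positive_token: str = POSITIVE,
    drop_cols: Iterable[str] = (),
    sep: str = ",",
) -> Dataset:
    """Read a delimited text table into a :class:`Dataset`."""
    frame = pd.read_csv(path, sep=sep)
    if label_col not in frame.columns:
        raise ValueError(f"label column {label_col!r} not found in the input")
    labels = np.where(
        frame[label_col].astype(str).str.strip() == str(positive_token),
        POSITIVE,
        NEGATIVE,
    )
    features = frame.drop(columns=[label_col, *[c for c in drop_cols if c in frame.columns]])
    return Dataset(
        features=features,
        labels=labels,
        feature_names=list(features.columns),
    )


def preprocess(raw: Dataset, drop_cols: Iterable[str] = ()) -> Dataset:
    """Impute and encode so every column is numeric with no missing cells.

    Numeric columns are median-imputed; non-numeric columns are
    mode-imputed and then integer-coded by sorted category order. Columns
    that are entirely missing are filled with zero so the column count is
    preserved. Deterministic given the input.
    """
    frame = raw.features.drop(
        columns=[c for c in drop_cols if c in raw.features.columns]
    ).copy()
    for col in frame.columns:
        series = frame[col]
        if pd.api.types.is_numeric_dtype(series):
            if series.isna().all():
                frame[col] = 0.0
            else:
                frame[col] = series.fillna(series.median())
        else:
            if series.isna().all():
                frame[col] = 0
            else:
                mode = series.mode(dropna=True).sort_values().iloc[0]
                filled = series.fillna(mode)
                categories = sorted(filled.astype(str).unique())
                codes = {cat: i for i, cat in enumerate(categories)}
                frame[col] = filled.astype(str).map(codes)
    frame = frame.astype(float)
    mask = raw.informative_mask
    if mask is not None and frame.shape[1] == raw.features.shape[1]:
        mask = mask.copy()
    elif mask is not None:
        keep = [raw.feature_names.index(c) for c in frame.columns]
        mask = mask[keep]
    return Dataset(
        features=frame,
        labels=raw.labels.copy(),
        feature_names=list(frame.columns),
        informative_mask=mask,
    )


def make_split(data: Dataset, cfg: SplitConfig = SplitConfig()) -> TrainTestSplit:
    """One stratified split per run so fitness values are comparable."""
    data.validate()
    x = data.features.to_numpy(dtype=float)
    x_train, x_test, y_train, y_test = train_test_split(
        x,
        data.labels,
        test_size=cfg.test_fraction,
        random_state=cfg.seed,
        stratify=data.labels,
    )
    return TrainTestSplit(x_train, x_test, y_train, y_test)


def nb_fitness(bits: np.ndarray, split: TrainTestSplit) -> float:
    """Percent test accuracy of Gaussian Naive Bayes on the selected columns."""
    bits = np.asarray(bits)
    if bits.sum() == 0:
        raise ValueError("cannot evaluate an empty feature subset")
    cols = np.flatnonzero(bits)
    model = GaussianNB(var_smoothing=1e-9)
    model.fit(split.x_train[:, cols], split.y_train)
    predicted = model.predict(split.x_test[:, cols])
    return float(accuracy_score(split.y_test, predicted)) * 100.0


def evaluate_metrics(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> MetricsReport:
    """Pooled (micro) and per-class-averaged (macro) precision/recall.

    The f-measure is the harmonic mean of macro precision and macro
    recall. Classes never predicted contribute precision 0 and are
    flagged in the report.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    classes = sorted(set(y_true.tolist()))
    accuracy = float(accuracy_score(y_true, y_pred)) * 100.0
    micro_p = float(precision_score(y_true, y_pred, labels=classes,
                                    average="micro", zero_division=0))
    micro_r = float(recall_score(y_true, y_pred, labels=classes,
                                 average="micro", zero_division=0))
    macro_p = float(precision_score(y_true, y_pred, labels=classes,
                                    average="macro", zero_division=0))
    macro_r = float(recall_score(y_true, y_pred, labels=classes,
                                 average="macro", zero_division=0))
    if macro_p + macro_r > 0:
        f_measure = 2.0 * macro_p * macro_r / (macro_p + macro_r)
    else:
        f_measure = 0.0
    missing = [c for c in classes if c not in set(y_pred.tolist())]
    return MetricsReport(
        accuracy=accuracy,
        micro_precision=micro_p,
        micro_recall=micro_r,
        macro_precision=macro_p,
        macro_recall=macro_r,
        f_measure=f_measure,
        zero_predicted_classes=missing,
    )


def execution_time_metric(n: int, z: int) -> int:
    """Cost proxy: agents times realized iterations."""
    if n < 0 or z < 0:
        raise ValueError("n and z must be non-negative")
    return n * z


@dataclass
class SelectionReport:
    result: BinaryRunResult
    selected_names: list[str]
    metrics: MetricsReport
    informative_overlap: int | None = None


def select_features(
    data: Dataset,
    config: RPOConfig,
    tcfg: TransferConfig = TransferConfig(),
    split_cfg: SplitConfig = SplitConfig(),
    *,
    early_stop_enabled: bool | None = None,
) -> SelectionReport:
    """Run the binary optimizer against the Naive Bayes fitness."""
    split = make_split(data, split_cfg)
    result = run_brpo(
        lambda bits: nb_fitness(bits, split),
        data.n_features,
        config,
        tcfg,
        early_stop_enabled=early_stop_enabled,
    )
    bits = result.best_bits
    cols = np.flatnonzero(bits)
    model = GaussianNB(var_smoothing=1e-9)
    model.fit(split.x_train[:, cols], split.y_train)
    predicted = model.predict(split.x_test[:, cols])
    metrics = evaluate_metrics(split.y_test, predicted)
    metrics.execution_time_metric = execution_time_metric(
        config.n, result.realized_iterations
    )
    overlap = None
    if data.informative_mask is not None:
        overlap = int(np.sum((bits == 1) & (data.informative_mask == 1)))
    return SelectionReport(
        result=result,
        selected_names=[data.feature_names[i] for i in cols],
        metrics=metrics,
        informative_overlap=overlap,
    )


def run_fs_experiment(
    data: Dataset,
    n_grid: Sequence[int],
    z_grid: Sequence[int],
    *,
    base_config: RPOConfig | None = None,
    tcfg: TransferConfig = TransferConfig(),
    split_cfg: SplitConfig = SplitConfig(),
) -> pd.DataFrame:
    """Run the selector over an (n, z) grid and tabulate the reports."""
    rows = []
    for n in n_grid:
        for z in z_grid:
            cfg = RPOConfig(
                n=n,
                z=z,
                xi=base_config.xi if base_config else min(4.0, n),
                k=base_config.k if base_config else None,
                b=base_config.b if base_config else 1.0,
                delta=base_config.delta if base_config else 0.0,
                n_ck=base_config.n_ck if base_config else 0,
                collision_enabled=base_config.collision_enabled if base_config else False,
                seed=base_config.seed if base_config else 0,
            )
            report = select_features(data, cfg, tcfg, split_cfg)
            row = {
                "n": n,
                "z": z,
                "n_selected": len(report.selected_names),
                "selected": ";".join(report.selected_names),
                **report.metrics.as_dict(),
            }
            row.pop("zero_predicted_classes")
            if report.informative_overlap is not None:
                row["informative_overlap"] = report.informative_overlap
            rows.append(row)
    return pd.DataFrame(rows)
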