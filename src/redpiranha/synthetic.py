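"""Synthetic clinical-style classification tables.

Emulates the shape of a wide laboratory-test dataset: a minority
positive class, many uninformative columns, a small informative subset
with a configurable standardized mean shift, a fraction of discretized
(categorical-looking) columns, and heavy missingness. Class-conditional
Gaussians keep the Bayes error of each informative feature available in
closed form for calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_selection import Dataset, NEGATIVE, POSITIVE

__all__ = ["SynthConfig", "generate_clinical", "write_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    n_samples: int = 5644
    n_features: int = 110
    n_informative: int = 10
    positive_fraction: float = 559 / 5644
    effect_size: float = 1.0
    missing_rate: float = 0.0
    categorical_fraction: float = 0.0
    n_bins: int = 4
    fixed_positive_count: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("cannot have more informative features than features")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive fraction must lie strictly between 0 and 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing rate must lie in [0, 1)")
        if not (0.0 <= self.categorical_fraction <= 1.0):
            raise ValueError("categorical fraction must lie in [0, 1]")


def generate_clinical(cfg: SynthConfig) -> Dataset:
    """Draw a labeled table per ``cfg``; deterministic given the seed.

    Labels are Bernoulli with the configured positive fraction (or an
    exact count when ``fixed_positive_count``). Informative columns are
    N(0,1) for negatives and N(effect_size, 1) for positives; the rest
    are N(0,1) regardless of class. A random ``categorical_fraction`` of
    columns is quantile-binned into integer codes, then missing cells
    are masked uniformly at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, f = cfg.n_samples, cfg.n_features

    if cfg.fixed_positive_count:
        n_pos = int(round(cfg.positive_fraction * n))
        labels01 = np.zeros(n, dtype=int)
        labels01[rng.permutation(n)[:n_pos]] = 1
    else:
        labels01 = (rng.random(n) < cfg.positive_fraction).astype(int)

    matrix = rng.standard_normal((n, f))
    informative = rng.permutation(f)[: cfg.n_informative]
    mask = np.zeros(f, dtype=int)
    mask[informative] = 1
    matrix[:, informative] += cfg.effect_size * labels01[:, None]

    n_cat = int(round(cfg.categorical_fraction * f))
    categorical = rng.permutation(f)[:n_cat]
    for col in categorical:
        edges = np.quantile(matrix[:, col], np.linspace(0, 1, cfg.n_bins + 1)[1:-1])
        matrix[:, col] = np.digitize(matrix[:, col], edges).astype(float)

    if cfg.missing_rate > 0:
        holes = rng.random((n, f)) < cfg.missing_rate
        matrix = np.where(holes, np.nan, matrix)

    names = [f"feat_{i:03d}" for i in range(f)]
    frame = pd.DataFrame(matrix, columns=names)
    labels = np.where(labels01 == 1, POSITIVE, NEGATIVE)
    return Dataset(
        features=frame,
        labels=labels,
        feature_names=names,
        informative_mask=mask,
    )


def write_dataset(data: Dataset, path, *, label_col: str = "label", sep: str = ",") -> None:
    """Write the table as delimited text with a header row."""
    frame = data.features.copy()
    frame[label_col] = data.labels
    frame.to_csv(path, sep=sep, index=False)
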