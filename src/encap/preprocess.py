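"""Robust scaling: per-feature centering by the median and scaling by the
interquartile range, fitted on training data only.

Quartiles use linear interpolation between order statistics (the common
default of mainstream numeric stacks).  Features with zero IQR are centered
but divided by 1, so constant columns map to exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoders import FeatureMatrix


class ScalerError(ValueError):
    pass


@dataclass
class ScalerParams:
    """Per-feature median, Q1 and Q3 plus the schema they were fitted on."""

    feature_names: list[str]
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray

    @property
    def iqr(self) -> np.ndarray:
        return self.q3 - self.q1

    @property
    def divisor(self) -> np.ndarray:
        d = self.iqr.copy()
        d[d == 0] = 1.0
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "median": self.median.tolist(),
                    "q1": self.q1.tolist(),
                    "q3": self.q3.tolist(),
                }
            )
        )

    @staticmethod
    def load(path: str | Path) -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return ScalerParams(
            d["feature_names"],
            np.array(d["median"]),
            np.array(d["q1"]),
            np.array(d["q3"]),
        )


def fit_robust_scaler(train: FeatureMatrix) -> ScalerParams:
    if train.values.shape[0] < 2:
        raise ScalerError("robust scaler requires at least 2 rows")
    x = train.values
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], axis=0)
    return ScalerParams(train.columns, med, q1, q3)


def _check_schema(params: ScalerParams, m: FeatureMatrix) -> None:
    if m.columns != params.feature_names:
        raise ScalerError("feature schema does not match fitted scaler")


def apply_scaler(params: ScalerParams, m: FeatureMatrix) -> FeatureMatrix:
    """Elementwise (x - median) / (Q3 - Q1) with stored training statistics."""
    _check_schema(params, m)
    scaled = (m.values - params.median) / params.divisor
    return FeatureMatrix(m.schema, scaled, list(m.row_ids))


def invert_scaler(params: ScalerParams, m: FeatureMatrix) -> FeatureMatrix:
    """Algebraic inverse of :func:`apply_scaler`."""
    _check_schema(params, m)
    raw = m.values * params.divisor + params.median
    return FeatureMatrix(m.schema, raw, list(m.row_ids))


def zero_variance_filter(m: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop constant columns; returns (filtered matrix, dropped names).

    Off by default throughout the pipeline; exposed because a full encoding
    of short peptides typically carries a handful of constant features.
    """
    keep = m.values.std(axis=0) > 0
    dropped = [n for n, k in zip(m.columns, keep) if not k]
    kept_names = [n for n, k in zip(m.columns, keep) if k]
    return m.select(kept_names), dropped
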