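"""Tracking-error metrics: RMSE, MAE and maximum absolute error.

All three are computed between a true displacement sequence ``y`` and a
predicted sequence ``y_hat`` and, throughout this package, are reported in
millimetres after destandardization.  For any input the ordering
``MAE <= RMSE <= MAX_AE`` holds (Jensen; max >= root-mean-square).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

AXES = ("x", "y", "z")

__all__ = ["rmse", "mae", "max_ae", "MetricsReport", "AXES"]


def _check(y, y_hat):
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty sequences")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root-mean-square error, sqrt(mean((y - y_hat)^2))."""
    y, y_hat = _check(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mae(y, y_hat) -> float:
    """Mean absolute error, mean(|y - y_hat|)."""
    y, y_hat = _check(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def max_ae(y, y_hat) -> float:
    """Maximum absolute error, max(|y - y_hat|)."""
    y, y_hat = _check(y, y_hat)
    return float(np.max(np.abs(y - y_hat)))


@dataclass
class MetricsReport:
    """Per-axis error report for one model evaluation.

    ``per_axis`` maps axis label -> {"rmse": .., "mae": .., "max_ae": ..},
    all in mm.  ``n`` is the number of evaluated samples per axis and
    ``context`` carries free-form labels (model kind, latency, dataset id).
    """

    per_axis: dict
    n: int
    context: dict = field(default_factory=dict)

    @classmethod
    def from_errors(cls, y_true_by_axis: Mapping[str, np.ndarray],
                    y_pred_by_axis: Mapping[str, np.ndarray],
                    context: dict | None = None) -> "MetricsReport":
        per_axis = {}
        n = 0
        for ax in y_true_by_axis:
            y, yh = y_true_by_axis[ax], y_pred_by_axis[ax]
            per_axis[ax] = {"rmse": rmse(y, yh), "mae": mae(y, yh),
                            "max_ae": max_ae(y, yh)}
            n = len(np.asarray(y))
        return cls(per_axis=per_axis, n=n, context=dict(context or {}))

    def metric(self, name: str, axis: str) -> float:
        return self.per_axis[axis][name]

    def pooled_rmse(self) -> float:
        """Root of the mean of per-axis mean squared errors."""
        return float(np.sqrt(np.mean([v["rmse"] ** 2
                                      for v in self.per_axis.values()])))

    def to_dict(self) -> dict:
        return {"per_axis": self.per_axis, "n": self.n, "context": self.context}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (axis, metric)."""
        rows = []
        for ax, vals in self.per_axis.items():
            for m, v in vals.items():
                rows.append({**self.context, "axis": ax, "metric": m,
                             "value_mm": v})
        return pd.DataFrame(rows)
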