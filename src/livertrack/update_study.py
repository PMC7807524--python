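"""Cumulative model-update verification protocol.

The session is cut chronologically into six contiguous parts C1..C6 in the
proportion 1:2:2:2:2:1.  Five assessments train the external/internal
correlator on the nested sets C1, C1+C2, ..., C1+..+C5 and always test on
C6; each assessment is repeated with fresh seeds and the mean RMSE/MAE over
repeats is reported, normalized to the fifth update.  On data whose
external/internal relation drifts over time, later updates train on samples
closer in time to the test segment, so the normalized error falls — the
rationale for refreshing the correlation model during a treatment session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lstm import NetworkConfig, TrainConfig
from .metrics import AXES, mae, rmse
from .svr import SVRConfig
from .tracking import AxisModel, _fit_axis_model, _train_stats, \
    make_correlation_dataset
from .signals import PairedTraces

__all__ = ["UpdateStudyConfig", "UpdateStudyResult", "split_six_parts",
           "run_update_study"]

DEFAULT_PROPORTIONS = (1, 2, 2, 2, 2, 1)


@dataclass(frozen=True)
class UpdateStudyConfig:
    """Protocol settings: split proportions, repeats and model settings."""

    proportions: tuple = DEFAULT_PROPORTIONS
    repeats: int = 5
    model_kind: str = "lstm"
    window: int = 20
    seed_base: int = 0
    net_config: NetworkConfig | None = None
    train_config: TrainConfig | None = None
    svr_config: SVRConfig | None = None

    def __post_init__(self):
        if len(self.proportions) != 6 or any(p <= 0 for p in self.proportions):
            raise ValueError("need six positive proportions")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def split_six_parts(paired: PairedTraces,
                    proportions=DEFAULT_PROPORTIONS) -> list:
    """Cut the session into six contiguous chronological segments.

    Lengths are proportional to ``proportions`` with largest-remainder
    rounding so they sum exactly to the trace length; concatenating the
    segments reproduces the original session.
    """
    n = len(paired)
    props = np.asarray(proportions, dtype=float)
    if n < 6 * 10:
        raise ValueError("trace too short to split into six usable parts")
    exact = props / props.sum() * n
    lengths = np.floor(exact).astype(int)
    rem = exact - lengths
    for k in np.argsort(-rem)[: n - lengths.sum()]:
        lengths[k] += 1
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    return [paired.slice(bounds[k], bounds[k + 1]) for k in range(6)]


@dataclass
class UpdateStudyResult:
    """Per-update mean and normalized RMSE/MAE, plus the raw repeats.

    Arrays are indexed [update k-1, axis]; ``raw_rmse``/``raw_mae`` add a
    leading repeat axis.  Normalization divides by the update-5 mean, so
    the fifth normalized value is exactly 1.
    """

    mean_rmse: np.ndarray       # (5, 3)
    mean_mae: np.ndarray        # (5, 3)
    norm_rmse: np.ndarray       # (5, 3)
    norm_mae: np.ndarray        # (5, 3)
    raw_rmse: np.ndarray        # (5, repeats, 3)
    raw_mae: np.ndarray         # (5, repeats, 3)
    config: UpdateStudyConfig | None = None

    def pooled_mean_rmse(self) -> np.ndarray:
        """Root-mean over axes of the per-axis mean RMSEs, one per update."""
        return np.sqrt(np.mean(self.mean_rmse ** 2, axis=1))

    def pooled_mean_mae(self) -> np.ndarray:
        return np.mean(self.mean_mae, axis=1)

    def to_dict(self) -> dict:
        return {
            "axes": list(AXES),
            "mean_rmse_mm": self.mean_rmse.tolist(),
            "mean_mae_mm": self.mean_mae.tolist(),
            "normalized_rmse": self.norm_rmse.tolist(),
            "normalized_mae": self.norm_mae.tolist(),
            "raw_rmse_mm": self.raw_rmse.tolist(),
            "raw_mae_mm": self.raw_mae.tolist(),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(5):
            for a, ax in enumerate(AXES):
                rows.append({
                    "update": k + 1, "axis": ax,
                    "rmse_mm": self.mean_rmse[k, a],
                    "mae_mm": self.mean_mae[k, a],
                    "rmse_normalized": self.norm_rmse[k, a],
                    "mae_normalized": self.norm_mae[k, a],
                })
        return pd.DataFrame(rows)


def run_update_study(paired: PairedTraces,
                     config: UpdateStudyConfig | None = None
                     ) -> UpdateStudyResult:
    """Run the five nested-training-set assessments against the fixed C6.

    For update k the correlator trains on the concatenation C1..Ck (with
    ``repeats`` independent seeds) and is evaluated on windows lying
    entirely inside C6, so the test segment is never seen in training.
    """
    config = config or UpdateStudyConfig()
    parts = split_six_parts(paired, config.proportions)
    bounds = np.cumsum([len(p) for p in parts])
    c6 = parts[5]
    test_ds = make_correlation_dataset(c6, config.window)

    repeats = config.repeats
    raw_rmse = np.empty((5, repeats, 3))
    raw_mae = np.empty((5, repeats, 3))
    for k in range(5):
        train_slice = paired.slice(0, bounds[k])
        train_ds = make_correlation_dataset(train_slice, config.window)
        for a, ax in enumerate(AXES):
            x_mean, x_std = _train_stats(train_slice.external.axis(ax),
                                         len(train_slice))
            y_mean, y_std = _train_stats(train_slice.internal.axis(ax),
                                         len(train_slice))
            aw = train_ds[ax]
            Xs = (aw.X - x_mean) / x_std
            ys = (aw.y - y_mean) / y_std
            tw = test_ds[ax]
            for r in range(repeats):
                seed = config.seed_base + 1000 * k + r
                model = _fit_axis_model(Xs, ys, config.model_kind,
                                        config.window, config.net_config,
                                        config.train_config,
                                        config.svr_config, seed)
                am = AxisModel(kind=config.model_kind, model=model,
                               x_mean=x_mean, x_std=x_std,
                               y_mean=y_mean, y_std=y_std)
                pred = am.predict(tw.X)
                raw_rmse[k, r, a] = rmse(tw.y, pred)
                raw_mae[k, r, a] = mae(tw.y, pred)

    mean_rmse = raw_rmse.mean(axis=1)
    mean_mae = raw_mae.mean(axis=1)
    return UpdateStudyResult(
        mean_rmse=mean_rmse, mean_mae=mean_mae,
        norm_rmse=mean_rmse / mean_rmse[4], norm_mae=mean_mae / mean_mae[4],
        raw_rmse=raw_rmse, raw_mae=raw_mae, config=config)
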