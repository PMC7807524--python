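"""Windowed datasets, model training and the integrated tracker.

Four model roles are trained here, each per axis and each available in an
LSTM and an SVR variant:

* external predictor (``LSTMpred``/``SVRpred``): maps a window of W
  chest-surface samples ending at time t to the surface position at
  t + i, where i is the system latency expressed in sampling steps;
* external/internal correlator (``LSTMcorr``/``SVRcorr``): maps a window
  of W surface samples ending at t to the liver position at t.

The integrated tracker composes the two: the predictor fills in the i
not-yet-observed surface samples, the correlator converts the completed
window into the liver position at t + i.  At i = 0 the composition reduces
exactly to the correlator.

Standardization statistics are always computed from the training portion
only and all reported metrics are in mm after destandardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .lstm import LSTMRegressor, NetworkConfig, TrainConfig
from .metrics import AXES, MetricsReport, rmse
from .signals import MotionTrace, PairedTraces
from .svr import SVRConfig, fit_svr, predict_svr

__all__ = [
    "LatencySpec", "AxisWindows", "WindowedDataset", "latency_to_steps",
    "make_prediction_dataset", "make_correlation_dataset",
    "chronological_split", "AxisModel", "ExternalPredictor", "Correlator",
    "train_external_predictor", "train_correlator", "IntegratedTracker",
    "build_integrated_tracker", "evaluate_integrated", "persistence_rmse",
]

MODEL_KINDS = ("lstm", "svr")


def latency_displacement_mm(latency_ms: float,
                            speed_mm_per_s: float = 20.0) -> float:
    """Worst-case positional uncertainty caused by an uncompensated latency.

    For a target moving at ``speed_mm_per_s`` (20 mm/s is the usual clinical
    planning speed for respiratory targets), a latency of L ms leaves the
    beam aimed where the target was L ms ago: uncertainty = speed * L.
    E.g. 100 ms -> 2 mm, 400 ms -> 8 mm.
    """
    if latency_ms < 0:
        raise ValueError("latency must be >= 0")
    return speed_mm_per_s * latency_ms / 1000.0


def latency_to_steps(latency_ms: float, sampling_rate_hz: float) -> int:
    """Latency in ms -> whole sampling steps (nearest integer, ties up).

    At 20 Hz: 50 ms -> 1, 150 ms -> 3, 200 ms -> 4, 450 ms -> 9.
    """
    if latency_ms < 0:
        raise ValueError("latency must be >= 0")
    return int(math.floor(latency_ms * sampling_rate_hz / 1000.0 + 0.5))


@dataclass(frozen=True)
class LatencySpec:
    """System latency and its step-count equivalent at a sampling rate."""

    latency_ms: float
    sampling_rate_hz: float = 20.0

    @property
    def steps(self) -> int:
        return latency_to_steps(self.latency_ms, self.sampling_rate_hz)


@dataclass
class AxisWindows:
    """Supervised pairs for one axis: window ending at t -> target at t+i."""

    X: np.ndarray              # (M, W)
    y: np.ndarray              # (M,)
    axis: str
    window: int
    steps: int
    target_indices: np.ndarray  # (M,) index of each target in the trace

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class WindowedDataset:
    """Per-axis supervised datasets sharing one (W, i) configuration."""

    axes: dict
    window: int
    steps: int

    def __getitem__(self, axis: str) -> AxisWindows:
        return self.axes[axis]

    def n_pairs(self) -> int:
        return len(next(iter(self.axes.values())))


def _window_series(x: np.ndarray, y_src: np.ndarray, W: int, i: int,
                   axis: str) -> AxisWindows:
    n = len(x)
    m = n - W - i + 1
    if m < 1:
        raise ValueError(f"trace too short: need >= {W + i} samples, got {n}")
    X = sliding_window_view(x, W)[:m].copy()
    tidx = np.arange(W - 1 + i, n)
    return AxisWindows(X=X, y=y_src[tidx].copy(), axis=axis, window=W,
                       steps=i, target_indices=tidx)


def make_prediction_dataset(trace: MotionTrace, window: int,
                            steps: int) -> WindowedDataset:
    """Windows of the external signal targeting the same signal i ahead.

    Window k covers samples [k, k+W) and targets sample k+W-1+i; the pair
    count is N - W - i + 1.
    """
    axes = {ax: _window_series(trace.axis(ax), trace.axis(ax), window, steps,
                               ax) for ax in AXES}
    return WindowedDataset(axes=axes, window=window, steps=steps)


def make_correlation_dataset(paired: PairedTraces,
                             window: int) -> WindowedDataset:
    """External windows ending at t targeting the internal sample at t.

    Axes are independent: the x-axis dataset reads only x samples of both
    traces.  Pair count is N - W + 1.
    """
    axes = {ax: _window_series(paired.external.axis(ax),
                               paired.internal.axis(ax), window, 0, ax)
            for ax in AXES}
    return WindowedDataset(axes=axes, window=window, steps=0)


def chronological_split(dataset: WindowedDataset, train_fraction: float = 0.9
                        ) -> tuple[WindowedDataset, WindowedDataset]:
    """Time-ordered split: first floor(fraction*M) pairs train, rest test."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    m = dataset.n_pairs()
    m_train = int(math.floor(train_fraction * m))
    if m_train < 1 or m_train >= m:
        raise ValueError("split leaves an empty side")

    def cut(ds, lo, hi):
        return WindowedDataset(
            axes={ax: AxisWindows(X=aw.X[lo:hi], y=aw.y[lo:hi], axis=ax,
                                  window=aw.window, steps=aw.steps,
                                  target_indices=aw.target_indices[lo:hi])
                  for ax, aw in ds.axes.items()},
            window=ds.window, steps=ds.steps)

    return cut(dataset, 0, m_train), cut(dataset, m_train, m)


# --------------------------------------------------------------- axis models

@dataclass
class AxisModel:
    """One trained per-axis model plus its standardization statistics.

    ``predict`` takes raw-mm windows, z-scores them with the training-set
    input stats, runs the model and maps the output back to mm with the
    target stats.  For the external predictor input and target stats
    coincide; for the correlator they are the external and internal stats.
    """

    kind: str
    model: object  # LSTMRegressor or SVRModel
    x_mean: float
    x_std: float
    y_mean: float
    y_std: float

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X_raw, dtype=float) - self.x_mean) / self.x_std
        if self.kind == "lstm":
            ps = self.model.forward(Xs)
        else:
            ps = predict_svr(self.model, Xs)
        return np.asarray(ps) * self.y_std + self.y_mean


def _fit_axis_model(X_std: np.ndarray, y_std: np.ndarray, kind: str,
                    window: int, net_config: NetworkConfig | None,
                    train_config: TrainConfig | None,
                    svr_config: SVRConfig | None, seed: int):
    if kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}")
    if kind == "lstm":
        cfg = net_config or NetworkConfig()
        if cfg.window != window:
            cfg = NetworkConfig(num_layers=cfg.num_layers,
                                hidden_size=cfg.hidden_size,
                                dropout=cfg.dropout, window=window,
                                use_biases=cfg.use_biases)
        tc = train_config or TrainConfig()
        tc = TrainConfig(learning_rate=tc.learning_rate,
                         batch_size=tc.batch_size, epochs=tc.epochs,
                         seed=seed)
        model = LSTMRegressor(cfg, seed=seed)
        model.fit(X_std, y_std, tc)
        return model
    return fit_svr(X_std, y_std, svr_config or SVRConfig())


@dataclass
class ExternalPredictor:
    """Per-axis latency-compensation models for the external signal."""

    axis_models: dict
    window: int
    latency: LatencySpec
    kind: str
    report: MetricsReport | None = None

    def predict_axis(self, axis: str, X_raw: np.ndarray) -> np.ndarray:
        return self.axis_models[axis].predict(X_raw)


@dataclass
class Correlator:
    """Per-axis external->internal correlation models."""

    axis_models: dict
    window: int
    kind: str
    report: MetricsReport | None = None

    def predict_axis(self, axis: str, X_raw: np.ndarray) -> np.ndarray:
        return self.axis_models[axis].predict(X_raw)


def _train_stats(series: np.ndarray, n_cover: int) -> tuple[float, float]:
    region = series[:n_cover]
    mean = float(region.mean())
    std = float(region.std())
    if std <= 0:
        raise ValueError("constant training region: cannot standardize")
    return mean, std


def train_external_predictor(trace: MotionTrace, model_kind: str,
                             latency: LatencySpec, *, window: int = 20,
                             train_fraction: float = 0.9,
                             net_config: NetworkConfig | None = None,
                             train_config: TrainConfig | None = None,
                             svr_config: SVRConfig | None = None,
                             seed: int = 0,
                             axes: tuple = AXES) -> ExternalPredictor:
    """Train per-axis i-step-ahead predictors on a 9:1 chronological split.

    Returns the predictor with a held-out :class:`MetricsReport` in mm.
    ``axes`` restricts training to a subset (e.g. the dominant
    superior-inferior axis) for single-axis studies.
    """
    i = latency.steps
    ds = make_prediction_dataset(trace, window, i)
    m_train = int(math.floor(train_fraction * ds.n_pairs()))
    if m_train < 1 or m_train >= ds.n_pairs():
        raise ValueError("split leaves an empty side")
    axis_models, y_true, y_pred = {}, {}, {}
    for k, ax in enumerate(axes):
        series = trace.axis(ax)
        mean, std = _train_stats(series, window + i + m_train - 1)
        aw = ds[ax]
        Xs = (aw.X - mean) / std
        ys = (aw.y - mean) / std
        model = _fit_axis_model(Xs[:m_train], ys[:m_train], model_kind,
                                window, net_config, train_config, svr_config,
                                seed + k)
        am = AxisModel(kind=model_kind, model=model, x_mean=mean, x_std=std,
                       y_mean=mean, y_std=std)
        axis_models[ax] = am
        y_true[ax] = aw.y[m_train:]
        y_pred[ax] = am.predict(aw.X[m_train:])
    report = MetricsReport.from_errors(y_true, y_pred, context={
        "model": f"{model_kind}_pred", "latency_ms": latency.latency_ms,
        "steps": i, "window": window})
    return ExternalPredictor(axis_models=axis_models, window=window,
                             latency=latency, kind=model_kind, report=report)


def train_correlator(paired: PairedTraces, model_kind: str, *,
                     window: int = 20, train_fraction: float = 0.9,
                     net_config: NetworkConfig | None = None,
                     train_config: TrainConfig | None = None,
                     svr_config: SVRConfig | None = None,
                     seed: int = 0,
                     axes: tuple = AXES) -> Correlator:
    """Train per-axis external->internal correlators (9:1 split)."""
    ds = make_correlation_dataset(paired, window)
    m_train = int(math.floor(train_fraction * ds.n_pairs()))
    if m_train < 1 or m_train >= ds.n_pairs():
        raise ValueError("split leaves an empty side")
    axis_models, y_true, y_pred = {}, {}, {}
    for k, ax in enumerate(axes):
        x_mean, x_std = _train_stats(paired.external.axis(ax),
                                     window + m_train - 1)
        y_mean, y_std = _train_stats(paired.internal.axis(ax),
                                     window + m_train - 1)
        aw = ds[ax]
        Xs = (aw.X - x_mean) / x_std
        ys = (aw.y - y_mean) / y_std
        model = _fit_axis_model(Xs[:m_train], ys[:m_train], model_kind,
                                window, net_config, train_config, svr_config,
                                seed + k)
        am = AxisModel(kind=model_kind, model=model, x_mean=x_mean,
                       x_std=x_std, y_mean=y_mean, y_std=y_std)
        axis_models[ax] = am
        y_true[ax] = aw.y[m_train:]
        y_pred[ax] = am.predict(aw.X[m_train:])
    report = MetricsReport.from_errors(y_true, y_pred, context={
        "model": f"{model_kind}_corr", "window": window})
    return Correlator(axis_models=axis_models, window=window,
                      kind=model_kind, report=report)


def persistence_rmse(trace: MotionTrace, window: int, steps: int,
                     train_fraction: float = 0.9) -> dict:
    """Held-out RMSE of the persistence baseline (predict S_t for S_{t+i})."""
    ds = make_prediction_dataset(trace, window, steps)
    _, test = chronological_split(ds, train_fraction)
    return {ax: rmse(test[ax].y, test[ax].X[:, -1]) for ax in AXES}


# ----------------------------------------------------------- integrated model

@dataclass
class IntegratedTracker:
    """Latency-compensated external->internal tracker.

    Combines a trained external predictor and a trained correlator from the
    same session.  For a target time t + i the correlator consumes a window
    of W external values ending at t + i in which the last min(i, W)
    entries are predictor outputs and the rest are observed samples.
    """

    predictor: ExternalPredictor
    correlator: Correlator

    def __post_init__(self):
        if self.predictor.window != self.correlator.window:
            raise ValueError("predictor and correlator window lengths differ")

    @property
    def window(self) -> int:
        return self.predictor.window

    @property
    def steps(self) -> int:
        return self.predictor.latency.steps

    def predict(self, external_history: np.ndarray) -> np.ndarray:
        """Predict the 3-axis internal position i steps past the last
        observed external sample.  ``external_history`` is (>= W+i, 3) mm."""
        W, i = self.window, self.steps
        h = np.asarray(external_history, dtype=float)
        if h.ndim != 2 or h.shape[1] != 3 or h.shape[0] < W + i:
            raise ValueError(f"history must be (>= {W + i}, 3)")
        out = np.empty(3)
        for a, ax in enumerate(AXES):
            s = h[:, a]
            if i > 0:
                # window ending at t+j-i is fully observed for j = 1..i
                anchors = np.stack([s[len(s) - (i - j) - W:
                                      len(s) - (i - j)] for j in range(1, i + 1)])
                preds = self.predictor.predict_axis(ax, anchors)
                full = np.concatenate([s, preds])
            else:
                full = s
            out[a] = float(self.correlator.predict_axis(ax, full[-W:]))
        return out

    def track(self, external: MotionTrace,
              start_index: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Predict the internal trace for every reachable target index.

        Returns (target_indices, predictions (K, 3) mm).  Target index j
        uses only external samples up to j - i.  ``start_index`` trims the
        output to targets >= start_index (e.g. a held-out region).
        """
        W, i = self.window, self.steps
        n = len(external)
        n_pred_cols = min(i, W)
        j0 = max(W - 1, W + i + n_pred_cols - 2)
        if start_index is not None:
            j0 = max(j0, start_index)
        if j0 > n - 1:
            raise ValueError("trace too short for any tracked target")
        targets = np.arange(j0, n)
        out = np.empty((len(targets), 3))
        for a, ax in enumerate(AXES):
            s = external.values[:, a]
            if i > 0:
                anchors = sliding_window_view(s, W)[:n - W - i + 1]
                preds = self.predictor.predict_axis(ax, anchors)
                # preds[m] is the forecast for trace index W - 1 + i + m
                def pred_at(k):
                    return preds[k - (W - 1 + i)]
            X_corr = np.empty((len(targets), W))
            for r, j in enumerate(targets):
                n_obs = W - n_pred_cols
                obs = s[j - i - n_obs + 1: j - i + 1]
                if i > 0:
                    fut = np.array([pred_at(k)
                                    for k in range(j - n_pred_cols + 1, j + 1)])
                    X_corr[r] = np.concatenate([obs, fut])
                else:
                    X_corr[r] = obs
            out[:, a] = self.correlator.predict_axis(ax, X_corr)
        return targets, out


def build_integrated_tracker(paired: PairedTraces, model_kind: str,
                             latency: LatencySpec, *, window: int = 20,
                             train_fraction: float = 0.9,
                             net_config: NetworkConfig | None = None,
                             pred_train_config: TrainConfig | None = None,
                             corr_train_config: TrainConfig | None = None,
                             svr_config: SVRConfig | None = None,
                             seed: int = 0) -> IntegratedTracker:
    """Train predictor and correlator on one session and compose them.

    The correlator's LSTM variant trains for 40 epochs versus the
    predictor's 60 (the correlation task converges faster), matching the
    two models' default training settings.
    """
    pred_tc = pred_train_config or TrainConfig(epochs=60)
    corr_tc = corr_train_config or TrainConfig(epochs=40)
    predictor = train_external_predictor(
        paired.external, model_kind, latency, window=window,
        train_fraction=train_fraction, net_config=net_config,
        train_config=pred_tc, svr_config=svr_config, seed=seed)
    correlator = train_correlator(
        paired, model_kind, window=window, train_fraction=train_fraction,
        net_config=net_config, train_config=corr_tc, svr_config=svr_config,
        seed=seed + 100)
    return IntegratedTracker(predictor=predictor, correlator=correlator)


def evaluate_integrated(tracker: IntegratedTracker, paired: PairedTraces,
                        start_index: int | None = None) -> MetricsReport:
    """Metrics (mm) of the integrated tracker against the internal trace."""
    targets, preds = tracker.track(paired.external, start_index=start_index)
    y_true = {ax: paired.internal.values[targets, a]
              for a, ax in enumerate(AXES)}
    y_pred = {ax: preds[:, a] for a, ax in enumerate(AXES)}
    return MetricsReport.from_errors(y_true, y_pred, context={
        "model": f"{tracker.predictor.kind}_integrated",
        "latency_ms": tracker.predictor.latency.latency_ms,
        "steps": tracker.steps, "window": tracker.window})
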