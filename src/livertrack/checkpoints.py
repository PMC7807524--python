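"""Self-describing JSON checkpoints for trained trackers.

One schema (versioned) covers both model families; a ``kind`` field
distinguishes the LSTM and SVR variants and a ``role`` field the external
predictor from the external/internal correlator.  Standardization
statistics travel with the weights so a loaded model consumes and emits
raw millimetres exactly like the one that was saved.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .lstm import LSTMRegressor
from .svr import SVRConfig, SVRModel
from .tracking import AxisModel, Correlator, ExternalPredictor, LatencySpec

SCHEMA_VERSION = 1

__all__ = ["save_model", "load_model", "SCHEMA_VERSION"]


def _axis_model_to_dict(am: AxisModel) -> dict:
    if am.kind == "lstm":
        payload = am.model.state_dict()
    else:
        payload = {
            "support_vectors": am.model.support_vectors.tolist(),
            "dual_coef": am.model.dual_coef.tolist(),
            "intercept": am.model.intercept,
            "config": asdict(am.model.config),
        }
    return {"kind": am.kind, "model": payload,
            "stats": {"x_mean": am.x_mean, "x_std": am.x_std,
                      "y_mean": am.y_mean, "y_std": am.y_std}}


def _axis_model_from_dict(d: dict) -> AxisModel:
    if d["kind"] == "lstm":
        model = LSTMRegressor.from_state_dict(d["model"])
    else:
        p = d["model"]
        model = SVRModel(support_vectors=np.array(p["support_vectors"]),
                         dual_coef=np.array(p["dual_coef"]),
                         intercept=p["intercept"],
                         config=SVRConfig(**p["config"]))
    s = d["stats"]
    return AxisModel(kind=d["kind"], model=model, x_mean=s["x_mean"],
                     x_std=s["x_std"], y_mean=s["y_mean"], y_std=s["y_std"])


def save_model(obj: ExternalPredictor | Correlator, path) -> None:
    """Write a predictor or correlator checkpoint."""
    if isinstance(obj, ExternalPredictor):
        head = {"role": "predictor",
                "latency_ms": obj.latency.latency_ms,
                "sampling_rate_hz": obj.latency.sampling_rate_hz}
    elif isinstance(obj, Correlator):
        head = {"role": "correlator"}
    else:
        raise TypeError(f"cannot checkpoint {type(obj).__name__}")
    doc = {"schema_version": SCHEMA_VERSION, "kind": obj.kind,
           "window": obj.window, **head,
           "axes": {ax: _axis_model_to_dict(am)
                    for ax, am in obj.axis_models.items()}}
    if obj.report is not None:
        doc["report"] = obj.report.to_dict()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ExternalPredictor | Correlator:
    """Read a checkpoint back into the matching container."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported checkpoint schema: "
                         f"{doc.get('schema_version')!r}")
    axis_models = {ax: _axis_model_from_dict(d)
                   for ax, d in doc["axes"].items()}
    if doc["role"] == "predictor":
        return ExternalPredictor(
            axis_models=axis_models, window=doc["window"], kind=doc["kind"],
            latency=LatencySpec(latency_ms=doc["latency_ms"],
                                sampling_rate_hz=doc["sampling_rate_hz"]))
    return Correlator(axis_models=axis_models, window=doc["window"],
                      kind=doc["kind"])
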