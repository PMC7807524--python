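"""Predict the surface signal ahead of the system latency.

Trains the SVR external predictor at the four clinically relevant
latencies and compares the held-out RMSE with the persistence baseline
(just emit the current value).  Error grows with latency; a trained
predictor stays far below persistence.  Swap "svr" for "lstm" for the
recurrent variant (slower, usually more accurate at long latencies).
"""

from livertrack import (BreathingParams, LatencySpec, simulate_session,
                        train_external_predictor)
from livertrack.tracking import persistence_rmse

trace = simulate_session(BreathingParams(duration_s=120.0),
                         seed=0).external

print("latency   steps   model RMSE   persistence RMSE   (y axis, mm)")
for ms in (50.0, 150.0, 200.0, 450.0):
    spec = LatencySpec(ms, trace.sampling_rate_hz)
    pred = train_external_predictor(trace, "svr", spec, seed=0, axes=("y",))
    base = persistence_rmse(trace, 20, spec.steps)["y"]
    print(f"{ms:6.0f} ms   {spec.steps:3d}   {pred.report.per_axis['y']['rmse']:10.3f}"
          f"   {base:16.3f}")
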