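# livertrack

Latency-compensated, indirect real-time tracking of liver motion from
chest-surface breathing signals, for surface-guided radiotherapy (SGRT)
motion management.

SGRT systems watch the patient's skin, not the tumour. Steering a beam at
a moving liver target from surface data alone requires solving two
problems at once: the system acts on measurements that are 50–450 ms old
(**latency**), and the surface is only a surrogate for the internal
anatomy (**external/internal correlation**). `livertrack` implements both
stages and their composition:

* **External predictor** (`LSTMpred` / `SVRpred`): from a window of
  W = 20 surface samples ending at time *t*, forecast the surface position
  at *t + i*, where *i* = round(latency × f_s) sampling steps
  (50/150/200/450 ms → i = 1/3/4/9 at 20 Hz).
* **External/internal correlator** (`LSTMcorr` / `SVRcorr`): from a
  window of surface samples ending at *t*, estimate the liver position
  *I_t*.
* **Integrated tracker**: the predictor fills in the *i* not-yet-observed
  surface samples, the correlator converts the completed window into
  *Î_{t+i}* — internal position prediction and latency compensation in a
  single step.

Two model families are provided. The recurrent one is a **peephole LSTM**
(input/forget gates read the previous cell value s_c^{t−1}, the output
gate reads the current s_c^t; diagonal peephole weights; sigmoid gates,
tanh cell input/output) trained by numpy backpropagation-through-time
with Adam (lr 0.001, batch 64, MSE). The kernel one is **ε-insensitive
support vector regression** with an RBF kernel (γ = 0.1, C = 1000),
f(x) = Σ(α̂_i − α_i) k(x_i, x) + b, with an exact dense-QP solver bundled
as test-time ground truth. Evaluation uses RMSE, MAE and MAX_AE per axis
in mm, plus a cumulative **model-update study** (train on growing
prefixes C1..Ck of the session, always test on the final segment C6,
normalize to the fifth update) quantifying why the correlation model
should be refreshed during treatment.

No clinical recordings ship with the package; a seeded generator produces
paired surface/liver sessions with realistic structure (Lujan cos⁴
waveform, cycle jitter, baseline drift, sensor noise, drifting affine
external→internal map), so everything is reproducible offline.

## Worked example

```python
from livertrack import (BreathingParams, CorrelationParams, LatencySpec,
                        simulate_session, train_external_predictor,
                        train_correlator, IntegratedTracker,
                        evaluate_integrated)

session = simulate_session(BreathingParams(duration_s=180.0),
                           CorrelationParams(), seed=0)
pred = train_external_predictor(session.external, "svr",
                                LatencySpec(latency_ms=150.0), seed=0)
corr = train_correlator(session, "svr", seed=0)
tracker = IntegratedTracker(predictor=pred, correlator=corr)
report = evaluate_integrated(tracker, session,
                             start_index=int(0.9 * len(session)))
for ax in ("x", "y", "z"):
    print(f"{ax}: predictor {pred.report.per_axis[ax]['rmse']:.3f} mm, "
          f"correlator {corr.report.per_axis[ax]['rmse']:.3f} mm, "
          f"integrated {report.per_axis[ax]['rmse']:.3f} mm")
```

prints (held-out errors on the final 10% of the session):

```
x: predictor 0.198 mm, correlator 0.080 mm, integrated 0.089 mm
y: predictor 0.287 mm, correlator 0.192 mm, integrated 0.215 mm
z: predictor 0.200 mm, correlator 0.102 mm, integrated 0.113 mm
```

Reading: compensating a 150 ms latency on the surface signal alone costs
~0.2–0.3 mm RMSE; mapping surface to liver costs ~0.1–0.2 mm; doing both
at once (the clinically relevant task) costs slightly more than the
correlator alone but far less than the sum of the two stages — the
predictor's error enters only through the freshest window samples and is
attenuated by the surface-to-liver gain. The superior–inferior axis (y)
has the largest amplitude and the largest absolute error.

The `examples/` directory has one short script per capability
(simulation, preprocessing, latency sweep, integrated tracking, update
study); each prints what it computes and what the numbers mean. A thin
CLI mirrors the pipeline:

```bash
livertrack simulate --duration-s 180 --seed 0 --out-prefix /tmp/s
livertrack train-pred /tmp/s_external.csv --model lstm --latency-ms 450 --ckpt /tmp/pred.json
livertrack train-corr /tmp/s_external.csv /tmp/s_internal.csv --model lstm --ckpt /tmp/corr.json
livertrack track /tmp/s_external.csv --pred /tmp/pred.json --corr /tmp/corr.json \
    --out-csv /tmp/tracked.csv --internal-csv /tmp/s_internal.csv
livertrack update-study /tmp/s_external.csv /tmp/s_internal.csv --out-json /tmp/upd.json
```

Traces are CSV files with header `time_s,x_mm,y_mm,z_mm`.

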