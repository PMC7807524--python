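# Methods

## Problem

During surface-guided radiotherapy (SGRT) of the liver the treatment
system can only observe the patient's chest surface. Steering the beam to
the tumour therefore needs two models working together:

1. an **external prediction model** that forecasts the surface signal
   `S_{t+i}` from a window of recent samples ending at `S_t`, where `i`
   is the system latency expressed in sampling steps (50–450 ms, i.e.
   1–9 steps at 20 Hz), and
2. an **external/internal correlation model** that maps a window of
   surface samples ending at time `t` to the internal liver position
   `I_t` (tracked clinically at a vessel bifurcation).

The **integrated tracker** composes them: the predictor fills in the `i`
not-yet-observed surface samples of the window ending at `t+i`, and the
correlator converts the completed window into `Î_{t+i}`. At `i = 0` the
composition is exactly the correlator; this identity is asserted in the
tests. Each of the three axes (x = left–right, y = superior–inferior,
z = anterior–posterior) is modelled independently; errors are reported
per axis as RMSE, MAE and MAX_AE in mm, always after mapping model output
back to physical units.

## Models

### Peephole LSTM

The recurrent unit is the peephole memory block: input and forget gates
read the *previous* cell value, the output gate reads the *current* one,
peephole weights are diagonal (one scalar per cell), `f` is the logistic
sigmoid and `g = h = tanh`. The bare cell carries no bias terms, so unit
tests can check it against scalar arithmetic; training enables per-gate
biases (forget bias initialised to 1).

Training is full backpropagation-through-time with Adam
(learning rate 0.001, batch 64, MSE loss), implemented directly in numpy;
the analytic gradients, including all peephole terms, are verified against
central finite differences to 1e-5 relative error in the test suite.
Dropout (default 20%) is applied between stacked layers during training
only. One integer seed fixes weight initialisation, batch shuffling and
dropout masks, making every training run bit-reproducible.

The default architecture is 2 stacked layers of 32 memory blocks with a
linear readout of the final hidden state. This size trains in tens of
seconds per axis on one CPU while leaving the inter-layer dropout
meaningful; wider layers gave no measurable accuracy benefit on the
synthetic sessions. The external predictor trains for 60 epochs, the
correlator for 40 — the correlation task converges faster.

### ε-SVR

The ε-insensitive support vector regressor uses an RBF kernel
`k(u,v) = exp(-γ‖u−v‖²)` with γ = 0.1, C = 1000 and tube half-width
ε = 0.1 on standardized data. Fitting is delegated to libsvm through
scikit-learn; the kernel and the decision function
`f(x) = Σ β_i k(x_i, x) + b` are evaluated by this package's own code. A
dense solve of the dual QP (`fit_svr_qp`, scipy trust-region with analytic
gradient/Hessian and KKT-based intercept) provides exact ground truth on
small instances; the test suite requires agreement of the two routes to
1e-4 at all training points and 1e-6 relative in the dual objective.

ε bounds the attainable precision: residuals inside the tube are
unpenalised, so on standardized data the fitted function is only pinned to
within ≈ 0.1 standard deviations (≈ 0.2 mm on a typical superior–inferior
axis). Tests that assert sub-0.05 mm recovery of a noise-free affine
relation therefore run the SVR with ε = 0.01; this is a property of the
loss, not a tuning of the study.

Solver stopping tolerance defaults to 1e-3 (libsvm's own default); the
oracle-equivalence tests tighten it to 1e-8. It is a numerical setting,
not a model parameter.

## Windowing and evaluation protocol

Supervised pairs are stride-1 sliding windows of W = 20 samples (1 s at
20 Hz). The "1:1 length ratio" between inputs and targets is realised as
one scalar target per window: the predictor targets the same axis `i`
steps past the window end, the correlator targets the internal sample at
the window end. Both model families see identical pairs. Splits are
chronological (first 90% of pairs train, last 10% test, no shuffling);
standardization statistics come from the training region only and are
applied unchanged to test data. Metrics are computed on destandardized
values in mm. The persistence baseline (emit `S_t` as the forecast of
`S_{t+i}`) is evaluated on the same held-out pairs.

Latency converts to steps by nearest-integer rounding (ties up), which
reproduces the 50/150/200/450 ms → 1/3/4/9 mapping at 20 Hz.

## Synthetic sessions

No acquisition data ships with the package; a seeded generator emulates
the structure of free-breathing volunteer sessions:

* **External trace** — Lujan-type `cos^{2n}` waveform (n = 2), the
  standard parametric breathing model: per cycle, the period is drawn as
  `N(4 s, 8%)` and a breath-depth factor `N(1, 10%)` shared by all axes
  scales per-axis amplitudes (x 1.5, y 8, z 4 mm; superior–inferior
  largest, left–right smallest, as for abdominal organ motion). A linear
  baseline drift (0.5 mm/min) and white sensor noise (0.05 mm RMS) are
  added. Default sessions are 5 min at 20 Hz (6000 samples per axis;
  durations up to 6 min, 7200 samples, are used in tests).
* **Internal trace** — a slowly drifting affine map of the lagged
  external trace:
  `I(t) = g(t)·S(t−lag) + offset + q·S(t−lag)² + noise`, with
  `g(t) = gain·(1 + drift·t/60)`, defaults gain 0.8, lag 150 ms, offset
  1 mm, drift 5%/min, noise 0.05 mm, q = 0. The linear gain drift is the
  simplest structure that makes later data genuinely more informative
  about the near future, which is what the update study measures.

Sub-seeding is fixed: the external generator uses `seed`, the internal
noise stream `seed + 1`. Identical (parameters, seed) give bit-identical
sessions.

What the generator does **not** emulate: hysteresis between inhale and
exhale paths, cough/talking events, cardiac motion, phase-dependent
(rather than affine) external/internal coupling, and measurement dropouts.
Passing tests on these sessions therefore demonstrate that the machinery
— windowing, training, composition, update protocol — behaves as the
method intends, not that clinical error magnitudes transfer; those depend
on the acquisition system and patient.

## Preprocessing

* Outlier handling is a Hampel filter (centred window 7, threshold
  3 × 1.4826 × rolling MAD) that *replaces* flagged samples with the
  rolling median, preserving uniform sampling for the windowing stage.
  Windows whose MAD is zero are locally constant; there any deviation is
  an outlier. Passes repeat until a fixpoint, so the operation is
  idempotent.
* Smoothing/filtering is a centred moving average (default width 5)
  followed by a zero-phase 4th-order Butterworth low-pass (default
  2 Hz — breathing energy lies below 1 Hz). Zero-phase filtering avoids
  introducing artificial latency; constant signals pass with unit gain.
* Resampling (to align external with internal length) is linear
  interpolation on a uniform grid with exact endpoint preservation.

## Update study

The session is cut chronologically into C1..C6 in proportion
1:2:2:2:2:1 (largest-remainder rounding). Five assessments train the
correlator from scratch on C1, C1+C2, …, C1+…+C5 and all test on C6;
each repeats 5 times with fresh seeds, and mean RMSE/MAE over repeats are
reported per axis, plus pooled across axes (root-mean for RMSE, mean for
MAE), normalized to the fifth update. Test windows lie entirely inside
C6, so the test segment is never touched during training. Retraining from
scratch (rather than warm-start fine-tuning) matches the repeated
independent assessments of the protocol; warm-start updating of an
existing model is available through the ordinary `fit` API.

## Problem sizes and numerical choices

Default study conditions (5-min sessions, 60/40 epochs, full latency set)
are used by the acceptance-style tests where the property under test
demands them. `scripts/acceptance.py` runs 3-min sessions for the latency
sweep and correlation stages, a 150 s session with 0.3/min gain drift and
a reduced correlator (1 layer × 16 units, 8 epochs, dropout 0) for the
update study, and reports the superior–inferior axis for the sweep —
sizes chosen so a complete from-scratch run finishes comfortably on one
CPU while leaving every qualitative conclusion (error growth with
latency, predictor skill over persistence, sub-additive integration,
monotone update improvement) unchanged.

Degenerate inputs are rejected rather than silently handled: constant
axes cannot be standardized, windows longer than the trace raise, a
latency below zero raises. Ties in latency rounding go up. The update
study's improvement factor is dataset-dependent by construction; the
package asserts its direction and normalization, not a particular
magnitude.

## Known limitations

* Per-axis independent models; no cross-axis coupling or joint 3-axis
  regression.
* The correlator consumes a single axis of the external signal; multi-axis
  input is not implemented.
* No streaming/online update every few seconds — the update study is the
  batch protocol above.
* The numpy LSTM targets CPU; there is no GPU path.
* ν-SVR and incremental SVR variants are out of scope.
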