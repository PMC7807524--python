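"""Seeded generator of paired chest-surface / liver breathing traces.

The generator emulates the structure of free-breathing volunteer sessions:
quasi-periodic breathing with cycle-to-cycle amplitude and period jitter,
slow baseline drift and additive sensor noise, plus an internal (liver)
trace obtained from the external one through a slowly drifting affine map
with a fixed phase lag and optional quadratic nonlinearity.

The waveform within each breathing cycle is the Lujan cos^(2n) model, the
standard parametric description of respiratory displacement: motion dwells
near exhale and moves quickly through inhale.  Axis amplitudes default to
superior-inferior largest and left-right smallest, the usual ordering for
abdominal organ motion.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .signals import MotionTrace, PairedTraces

__all__ = ["BreathingParams", "CorrelationParams",
           "simulate_external", "derive_internal", "simulate_session"]


@dataclass(frozen=True)
class BreathingParams:
    """Parameters of the external (chest-surface) breathing generator.

    Defaults describe a 5-minute session at 20 Hz with a 4 s breathing
    period, ~10% cycle-to-cycle variability, half a millimetre of baseline
    drift per minute and 0.05 mm RMS sensor noise.
    """

    duration_s: float = 300.0
    sampling_rate_hz: float = 20.0
    amplitude_mm: tuple = (1.5, 8.0, 4.0)  # (x=LR, y=SI, z=AP)
    mean_period_s: float = 4.0
    period_jitter_sd: float = 0.08       # fractional
    amplitude_jitter_sd: float = 0.10    # fractional
    lujan_exponent: int = 2              # waveform is cos^(2n)
    baseline_drift_mm_per_min: float = 0.5
    noise_sd_mm: float = 0.05

    def __post_init__(self):
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if any(a < 0 for a in self.amplitude_mm):
            raise ValueError("amplitudes must be non-negative")
        if self.mean_period_s <= 0:
            raise ValueError("mean_period_s must be positive")
        if not 0 <= self.period_jitter_sd < 0.5:
            raise ValueError("period_jitter_sd must be in [0, 0.5)")
        if self.amplitude_jitter_sd < 0 or self.noise_sd_mm < 0:
            raise ValueError("jitter/noise SDs must be non-negative")
        if self.lujan_exponent < 1:
            raise ValueError("lujan_exponent must be >= 1")
        if self.sampling_rate_hz < 2.0 / self.mean_period_s:
            raise ValueError("sampling rate below breathing Nyquist")


@dataclass(frozen=True)
class CorrelationParams:
    """External -> internal map: internal(t) =
    gain(t) * external(t - lag) + offset + q * external(t - lag)^2 + noise,
    with gain(t) = gain * (1 + gain_drift_per_min * t / 60).

    The drifting gain emulates the slowly changing spatiotemporal relation
    between surface and organ motion that motivates online model updating.
    """

    gain: tuple = (0.8, 0.8, 0.8)
    gain_drift_per_min: float = 0.05     # fractional change per minute
    lag_s: float = 0.15
    offset_mm: float = 1.0
    internal_noise_sd_mm: float = 0.05
    nonlinearity: float = 0.0            # quadratic coefficient q (1/mm)

    def __post_init__(self):
        if any(g <= 0 for g in np.atleast_1d(self.gain)):
            raise ValueError("gain must be positive")
        if self.internal_noise_sd_mm < 0:
            raise ValueError("noise SD must be non-negative")


def _cycle_schedule(params: BreathingParams, rng: np.random.Generator):
    """Draw per-cycle (start_time, period, depth_factor) covering the session.

    The depth factor is shared across axes: one breath has one depth.
    """
    starts, periods, depths = [], [], []
    t = 0.0
    while t < params.duration_s:
        tau = params.mean_period_s * (
            1.0 + params.period_jitter_sd * rng.standard_normal())
        tau = max(tau, 0.2 * params.mean_period_s)
        depth = 1.0 + params.amplitude_jitter_sd * rng.standard_normal()
        starts.append(t)
        periods.append(tau)
        depths.append(max(depth, 0.0))
        t += tau
    return np.array(starts), np.array(periods), np.array(depths)


def simulate_external(params: BreathingParams, seed: int) -> MotionTrace:
    """Generate the external chest-surface trace.

    Deterministic for fixed (params, seed).  Cycle k has period
    tau_k ~ N(mean_period, jitter) and per-axis amplitude
    a_k = amplitude * depth_k with depth_k ~ N(1, amplitude_jitter);
    within the cycle the displacement is a_k * cos^(2n)(pi t' / tau_k)
    plus linear baseline drift and white Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.sampling_rate_hz))
    t = np.arange(n) / params.sampling_rate_hz
    starts, periods, depths = _cycle_schedule(params, rng)

    idx = np.searchsorted(starts, t, side="right") - 1
    tprime = t - starts[idx]
    phase = np.cos(np.pi * tprime / periods[idx]) ** (2 * params.lujan_exponent)
    drift = params.baseline_drift_mm_per_min * t / 60.0

    values = np.empty((n, 3))
    for a in range(3):
        amp = params.amplitude_mm[a] * depths[idx]
        noise = params.noise_sd_mm * rng.standard_normal(n)
        values[:, a] = amp * phase + drift + noise
    return MotionTrace(values, sampling_rate_hz=params.sampling_rate_hz)


def derive_internal(external: MotionTrace, corr: CorrelationParams,
                    seed: int) -> MotionTrace:
    """Derive the internal (liver) trace from an external one.

    The lag is applied by linear interpolation in time (edge-clamped);
    noise-free, drift-free settings make the map a deterministic function
    of the external trace regardless of the seed.
    """
    if abs(corr.lag_s) >= external.duration_s:
        raise ValueError("lag exceeds trace duration")
    rng = np.random.default_rng(seed)
    t = np.arange(len(external)) / external.sampling_rate_hz
    gains = np.atleast_1d(np.asarray(corr.gain, dtype=float))
    if gains.size == 1:
        gains = np.repeat(gains, 3)
    g_t = 1.0 + corr.gain_drift_per_min * t / 60.0

    values = np.empty_like(external.values)
    for a in range(3):
        lagged = np.interp(t - corr.lag_s, t, external.values[:, a])
        clean = (gains[a] * g_t * lagged + corr.offset_mm
                 + corr.nonlinearity * lagged ** 2)
        if corr.internal_noise_sd_mm > 0:
            clean = clean + corr.internal_noise_sd_mm * rng.standard_normal(
                len(external))
        values[:, a] = clean
    return MotionTrace(values, sampling_rate_hz=external.sampling_rate_hz,
                       start_time_s=external.start_time_s)


def simulate_session(params: BreathingParams | None = None,
                     corr: CorrelationParams | None = None,
                     seed: int = 0) -> PairedTraces:
    """Generate a full paired session.

    Sub-seeds: the external generator uses ``seed``, the internal noise
    stream uses ``seed + 1`` — fixed so sessions are fully reproducible.
    """
    params = params or BreathingParams()
    corr = corr or CorrelationParams()
    external = simulate_external(params, seed)
    internal = derive_internal(external, corr, seed + 1)
    return PairedTraces(external=external, internal=internal)


def params_to_dict(params: BreathingParams, corr: CorrelationParams,
                   seed: int) -> dict:
    """Ground-truth sidecar (YAML-serializable) for recovery tests."""
    d = {"breathing": asdict(params), "correlation": asdict(corr),
         "seed": int(seed)}
    d["breathing"]["amplitude_mm"] = [float(a) for a in params.amplitude_mm]
    d["correlation"]["gain"] = [float(g) for g in np.atleast_1d(corr.gain)]
    return d
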