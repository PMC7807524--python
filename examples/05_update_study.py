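"""Why the external/internal correlation model needs refreshing.

On a session whose surface-to-liver gain drifts over time, the study
trains the correlator on growing prefixes C1, C1+C2, ..., C1+...+C5 of
the session and always tests on the final segment C6.  Later updates
train on data closer in time to the test segment, so the error falls;
values are normalized to the fifth update.
"""

import numpy as np

from livertrack import (BreathingParams, CorrelationParams, NetworkConfig,
                        TrainConfig, simulate_session)
from livertrack.update_study import UpdateStudyConfig, run_update_study

paired = simulate_session(BreathingParams(duration_s=150.0),
                          CorrelationParams(gain_drift_per_min=0.3), seed=5)
cfg = UpdateStudyConfig(
    model_kind="lstm", repeats=3, seed_base=0,
    net_config=NetworkConfig(num_layers=1, hidden_size=16, dropout=0.0,
                             window=20),
    train_config=TrainConfig(epochs=8))
result = run_update_study(paired, cfg)

pooled = result.pooled_mean_rmse()
print("update   pooled RMSE (mm)   normalized to 5th")
for k in range(5):
    print(f"  {k + 1}      {pooled[k]:12.3f}       {pooled[k] / pooled[4]:10.2f}")
print(f"first-to-fifth improvement factor: {pooled[0] / pooled[4]:.1f}x")
print(np.round(result.to_frame().head(6), 3).to_string(index=False))
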