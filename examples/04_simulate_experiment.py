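"""Simulate the measurable outputs of a lexical-decision MEG session.

Window amplitudes of four evoked components (occipital ~100 ms,
occipito-temporal ~150 ms, left/right temporal ~400 ms) are linear in
standardized predictors, with per-participant gain/offset and trial
noise; reaction times follow the same linear form on a millisecond
scale. The study's validity rules are then applied: correct response
within 350-1500 ms, and participants need 290-of-360-scaled valid
trials.
"""

import numpy as np
import pandas as pd

from morphsurprisal import synth_responses as S
from morphsurprisal.defaults import DEFAULT_PREDICTOR_CORRELATIONS

cfg = S.load_components()
X = S.simulate_predictors_from_correlations(
    DEFAULT_PREDICTOR_CORRELATIONS, 360, seed=1
)

tensor = S.simulate_amplitudes(X, cfg["components"], n_participants=20, seed=2)
print(f"amplitudes: {tensor.values.shape} (item x participant x component)")
for c, name in enumerate(tensor.components):
    m = tensor.values[:, :, c]
    print(f"  {name:18s} mean {m.mean():6.2f} nAm, SD {m.std():5.2f}")

beh = cfg["behavior"]
noise_ms = beh["rt_scale_ms"] * S.calibrate_noise_sd(
    beh["rt_betas"], beh["target_r2"], X.corr(), n_participants=20
)
trials = S.simulate_behavior(
    X, beh["rt_betas"], beh["rt_baseline_ms"], noise_ms,
    accuracy_p=beh["accuracy_mean"], accuracy_sd=beh["accuracy_sd"],
    n_participants=20, seed=3, rt_scale_ms=beh["rt_scale_ms"],
)
rts = np.array([t.rt_ms for t in trials])
acc = np.mean([t.correct for t in trials])
print(f"\ntrials: {len(trials)}; mean RT {rts.mean():.0f} ms "
      f"(SD {rts.std():.0f}), accuracy {acc:.2f}")

kept, log = S.apply_trial_filters(trials)
retained, counts = S.apply_participant_filter(trials)
print(f"kept {len(kept)} trials; rejections: {dict(log)}")
print(f"participants retained: {len(retained)}/20 "
      f"(min valid count {min(counts.values())})")
# Trial noise is calibrated so the planted model R2 re-emerges at the
# item level after cross-participant averaging, mirroring how such
# studies report explained variance.
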