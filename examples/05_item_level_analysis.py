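"""Run the full item-level analysis on a simulated experiment.

Pipeline: trial validity filters -> participant filter -> per-item mean
RT; within-participant z-scoring of window amplitudes -> cross-
participant item averages; then, per target, simple correlations with
F(1, n-2) tests and forward stepwise regression with standardized
coefficients.
"""

import pandas as pd

from morphsurprisal import item_analysis as IA
from morphsurprisal import synth_responses as S
from morphsurprisal.defaults import DEFAULT_PREDICTOR_CORRELATIONS
from morphsurprisal.predictors import PredictorMatrix

cfg = S.load_components()
X = S.simulate_predictors_from_correlations(
    DEFAULT_PREDICTOR_CORRELATIONS, 360, seed=1
)
X.index = [f"w{i}" for i in range(len(X))]
matrix = PredictorMatrix(X, pd.DataFrame(True, index=X.index, columns=X.columns))

tensor = S.simulate_amplitudes(X, cfg["components"], n_participants=20, seed=2)
beh = cfg["behavior"]
noise_ms = beh["rt_scale_ms"] * S.calibrate_noise_sd(
    beh["rt_betas"], beh["target_r2"], X.corr(), n_participants=20
)
trials = S.simulate_behavior(
    X, beh["rt_betas"], beh["rt_baseline_ms"], noise_ms,
    n_participants=20, seed=3, rt_scale_ms=beh["rt_scale_ms"],
)
trials_df = pd.DataFrame(
    [(t.participant, t.item, t.rt_ms, int(t.correct)) for t in trials],
    columns=["participant", "item", "rt_ms", "correct"],
)

reports = IA.analyze(matrix, tensor.to_long(), trials_df)
print(f"{'target':18s} {'R2':>5s}  selected predictors (standardized beta)")
for target, rep in reports["words"].items():
    sel = ", ".join(f"{k}={v:+.2f}" for k, v in rep.betas.items())
    print(f"{target:18s} {rep.r2:5.2f}  {sel}")
# With the default effect sizes the analysis re-selects the planted
# predictors per component (length for the occipital window, length +
# bigram surprisal for the occipito-temporal window, the morph/surface
# surprisals for the temporal windows). RT results sit below the
# configured R2 and may admit extra predictors: the 350-1500 ms trial
# filters range-restrict exactly the high-surprisal items, which is a
# property of the study design the simulation reproduces.
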