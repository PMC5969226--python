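"""Default study conditions for the lexical-decision simulator.

These constants encode the reference effect structure the simulator
emulates: the pairwise correlations among the seven item-level
predictors, the standardized regression coefficients (and model R²)
linking predictors to each evoked component and to reaction time, and
the behavioral summary statistics (baseline RT, accuracy). Simulations
seeded from them should reproduce, as a matter of internal consistency,
the simple correlations listed in :data:`EXPECTED_SIMPLE_CORRELATIONS`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TABLE1_PREDICTOR_NAMES",
    "DEFAULT_PREDICTOR_CORRELATIONS",
    "EFFECT_SIZES",
    "EXPECTED_SIMPLE_CORRELATIONS",
    "RT_BASELINE_MS",
    "RT_SD_MS",
    "ACCURACY_MEAN",
    "ACCURACY_SD",
    "OCCIPITAL_SLOPE_NAM_PER_LETTER",
    "N_ITEMS",
    "N_PARTICIPANTS",
    "LENGTH_RANGE",
    "LENGTH_MEAN",
    "LENGTH_SD",
    "RT_MIN_MS",
    "RT_MAX_MS",
    "MIN_VALID_TRIALS",
]

#: Predictor order used by the correlation matrix (matrix-column order of
#: the predictor matrix).
TABLE1_PREDICTOR_NAMES = (
    "image_complexity",
    "length",
    "bigram_surprisal_bits",
    "tpl",
    "mdl_surprisal_bits",
    "lemma_surprisal_bits",
    "surface_surprisal_bits",
)

_R = np.array(
    [
        #  IC     len    bigr   tpl    mdl    lemma  surf
        [1.00,  0.81, -0.07, -0.06,  0.42,  0.05,  0.27],
        [0.81,  1.00,  0.09, -0.05,  0.54,  0.06,  0.34],
        [-0.07, 0.09,  1.00,  0.06,  0.06, -0.08,  0.09],
        [-0.06, -0.05, 0.06,  1.00,  0.01,  0.61, -0.10],
        [0.42,  0.54,  0.06,  0.01,  1.00,  0.38,  0.74],
        [0.05,  0.06, -0.08,  0.61,  0.38,  1.00,  0.40],
        [0.27,  0.34,  0.09, -0.10,  0.74,  0.40,  1.00],
    ]
)

#: Pairwise correlations among the seven predictors on the word stimuli.
DEFAULT_PREDICTOR_CORRELATIONS = pd.DataFrame(
    _R, index=list(TABLE1_PREDICTOR_NAMES), columns=list(TABLE1_PREDICTOR_NAMES)
)

#: Standardized multiple-regression coefficients and total model R² per
#: analysis target, word stimuli. Only the predictors a target selects
#: carry coefficients.
EFFECT_SIZES: dict[str, dict] = {
    "occipital": {
        "betas": {"length": 0.30},
        "r2": 0.09,
    },
    "occipito_temporal": {
        "betas": {"length": -0.15, "bigram_surprisal_bits": -0.14},
        "r2": 0.04,
    },
    "left_temporal": {
        "betas": {
            "image_complexity": -0.15,
            "mdl_surprisal_bits": 0.22,
            "surface_surprisal_bits": 0.22,
        },
        "r2": 0.15,
    },
    "right_temporal": {
        "betas": {
            "image_complexity": -0.24,
            "length": 0.33,
            "mdl_surprisal_bits": 0.21,
        },
        "r2": 0.12,
    },
    "reaction_time": {
        "betas": {
            "length": 0.36,
            "bigram_surprisal_bits": -0.11,
            "mdl_surprisal_bits": 0.20,
            "lemma_surprisal_bits": 0.14,
            "surface_surprisal_bits": 0.21,
        },
        "r2": 0.52,
    },
}

#: Headline simple correlations the default effect structure should
#: reconstruct (word stimuli): predictor -> target -> r.
EXPECTED_SIMPLE_CORRELATIONS: dict[str, dict[str, float]] = {
    "reaction_time": {"mdl_surprisal_bits": 0.61, "length": 0.57},
    "left_temporal": {"surface_surprisal_bits": 0.35, "mdl_surprisal_bits": 0.32},
    "occipital": {"length": 0.31},
}

# behavioral conditions
RT_BASELINE_MS = 852.0  #: mean word reaction time, ms
RT_SD_MS = 95.0  #: between-item/participant RT spread, ms
ACCURACY_MEAN = 0.92  #: mean proportion correct
ACCURACY_SD = 0.04  #: between-participant SD of proportion correct

#: Raw occipital amplitude gain per added letter, nAm/letter.
OCCIPITAL_SLOPE_NAM_PER_LETTER = 0.5

# experiment dimensions
N_ITEMS = 360
N_PARTICIPANTS = 20
LENGTH_RANGE = (4, 16)
LENGTH_MEAN = 10.3
LENGTH_SD = 2.8

# trial/participant validity rules
RT_MIN_MS = 350.0
RT_MAX_MS = 1500.0
MIN_VALID_TRIALS = 290


def implied_simple_correlation(
    target: str, predictor: str, corr: pd.DataFrame | None = None
) -> float:
    """Population simple correlation implied by the default effect sizes.

    For y = X beta + noise with standardized predictors correlated as
    ``corr`` and noise calibrated so the model R² matches the target's,
    corr(x_j, y) = (R beta)_j / sd(y) with sd(y)² = beta'R beta / R².
    """
    if corr is None:
        corr = DEFAULT_PREDICTOR_CORRELATIONS
    spec = EFFECT_SIZES[target]
    names = list(spec["betas"])
    if predictor not in names:
        names = names + [predictor]
    R = corr.loc[names, names].to_numpy()
    beta = np.array([spec["betas"].get(n, 0.0) for n in names])
    explained = beta @ R @ beta
    var_y = explained / spec["r2"]
    cov = (R @ beta)[names.index(predictor)]
    return float(cov / np.sqrt(var_y))
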