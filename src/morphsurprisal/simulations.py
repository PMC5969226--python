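"""Internal-consistency simulations of the simulated study.

Human MEG and reaction-time data are not regenerable, so the pipeline is
validated by consistency: draw predictors with the default correlation
structure, generate responses from the default standardized effect sizes
with noise calibrated to each target's model R², re-run the analysis,
and check that the implied study-level summary statistics re-emerge.
These functions are used both by the test suite and by the results
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults as D
from .corpus_stimuli import derive_seed, sample_stimulus_set
from .pipeline import build_study_corpus
from .synth_responses import (
    ComponentSpec,
    calibrate_noise_sd,
    simulate_amplitudes,
    simulate_predictors_from_correlations,
)

__all__ = [
    "simulate_target_responses",
    "reconstruct_simple_correlation",
    "reconstruct_full_model_r2",
    "recover_planted_betas",
    "recover_occipital_slope",
    "stimulus_length_mean",
]


def simulate_target_responses(
    target: str,
    n_items: int,
    seed: int,
    extra_predictors: tuple[str, ...] = (),
    n_participants: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One replicate of the item-level generative model for a target.

    Draws standardized predictors with the default correlation
    structure, forms the linear signal from the target's standardized
    coefficients, and adds Gaussian item-level noise whose variance is
    solved so the population model R² equals the target's. With
    ``n_participants`` > 1 the noise is the average of that many
    independent per-trial draws whose item-average variance meets the
    target (the value of extra participants is already folded in).
    Returns (predictor frame, response vector).
    """
    spec = D.EFFECT_SIZES[target]
    names = list(spec["betas"])
    for p in extra_predictors:
        if p not in names:
            names.append(p)
    corr = D.DEFAULT_PREDICTOR_CORRELATIONS.loc[names, names]
    X = simulate_predictors_from_correlations(corr, n_items, seed=seed)
    beta = np.array([spec["betas"].get(n, 0.0) for n in names])
    trial_sd = calibrate_noise_sd(
        spec["betas"], spec["r2"], corr, n_participants=n_participants
    )
    rng = np.random.default_rng(derive_seed(seed, f"noise-{target}"))
    noise = rng.normal(0.0, trial_sd, size=(n_items, n_participants)).mean(axis=1)
    y = X[names].to_numpy() @ beta + noise
    return X, y


def reconstruct_simple_correlation(
    target: str,
    predictor: str,
    n_items: int = 360,
    n_reps: int = 100,
    seed: int = 0,
) -> float:
    """Mean Pearson r between one predictor and the simulated response
    across seeded replicates of the target's generative model."""
    rs = []
    for rep in range(n_reps):
        X, y = simulate_target_responses(
            target, n_items, derive_seed(seed, f"rep{rep}"), (predictor,)
        )
        r, _ = stats.pearsonr(X[predictor], y)
        rs.append(r)
    return float(np.mean(rs))


def reconstruct_full_model_r2(
    target: str = "reaction_time",
    n_items: int = 360,
    n_reps: int = 100,
    seed: int = 0,
) -> float:
    """Mean R² of the full multiple regression refit on simulated
    responses across replicates."""
    r2s = []
    for rep in range(n_reps):
        X, y = simulate_target_responses(target, n_items, derive_seed(seed, f"rep{rep}"))
        A = np.column_stack([np.ones(n_items), X.to_numpy()])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        r2s.append(1 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))
    return float(np.mean(r2s))


def recover_planted_betas(
    target: str,
    n_items: int = 360,
    n_participants: int = 20,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery simulation for one target's planted effects.

    Each replicate simulates item-level responses (trial noise averaged
    over participants) and refits OLS of the response on the planted
    standardized predictors. Returns per-predictor planted value, mean
    recovered coefficient, and the standard error of that mean.
    """
    spec = D.EFFECT_SIZES[target]
    names = list(spec["betas"])
    est = np.empty((n_reps, len(names)))
    for rep in range(n_reps):
        X, y = simulate_target_responses(
            target,
            n_items,
            derive_seed(seed, f"rep{rep}"),
            n_participants=n_participants,
        )
        A = np.column_stack([np.ones(n_items), X[names].to_numpy()])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        est[rep] = coef[1:]
    return pd.DataFrame(
        {
            "planted": [spec["betas"][n] for n in names],
            "recovered": est.mean(axis=0),
            "sem": est.std(axis=0, ddof=1) / np.sqrt(n_reps),
        },
        index=names,
    )


def recover_occipital_slope(
    slope_nam_per_letter: float = D.OCCIPITAL_SLOPE_NAM_PER_LETTER,
    n_items: int = 360,
    n_participants: int = 20,
    trial_noise_sd: float = 3.0,
    n_reps: int = 50,
    seed: int = 0,
) -> float:
    """Recover the per-letter occipital amplitude slope in nAm/letter.

    Raw (non-z-scored) window amplitudes for items of lengths 4-16 are
    simulated with the planted slope and per-trial noise, averaged over
    participants per item, and regressed on length; returns the mean OLS
    slope across replicates.
    """
    lengths = np.tile(np.arange(4, 17), n_items // 13 + 1)[:n_items].astype(float)
    X = pd.DataFrame({"length": lengths}, index=[str(i) for i in range(n_items)])
    comp = ComponentSpec(
        name="occipital",
        peak_latency_ms=100,
        window_ms=(80, 120),
        baseline_nAm=15.0,
        betas={"length": slope_nam_per_letter},
        trial_noise_sd=trial_noise_sd,
        offset_sd=0.0,
        gain_sigma=0.0,
    )
    slopes = []
    for rep in range(n_reps):
        tensor = simulate_amplitudes(
            X, [comp], n_participants, seed=derive_seed(seed, f"rep{rep}")
        )
        item_mean = tensor.values[:, :, 0].mean(axis=1)
        fit = stats.linregress(lengths, item_mean)
        slopes.append(fit.slope)
    return float(np.mean(slopes))


def stimulus_length_mean(
    seed: int = 0,
    n_items: int = D.N_ITEMS,
    n_tokens: int = 200_000,
) -> float:
    """Mean letter length of a sampled synthetic stimulus set."""
    freq, _ = build_study_corpus(seed=derive_seed(seed, "corpus"), n_tokens=n_tokens)
    items = sample_stimulus_set(
        freq,
        n_items,
        D.LENGTH_RANGE,
        seed=derive_seed(seed, "sample"),
        target_mean=D.LENGTH_MEAN,
        target_sd=D.LENGTH_SD,
    )
    return float(np.mean([it.length_N for it in items]))
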