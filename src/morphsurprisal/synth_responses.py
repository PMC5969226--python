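"""Simulated lexical-decision responses: evoked amplitudes, RT, accuracy.

The generative model plants linear predictor effects in each evoked
component's analysis-window amplitude and in reaction time:

    amplitude(i, s, c) = gain_sc * (baseline_c + sum_j beta_cj x_ij
                                    + trial noise) + offset_sc

with per-participant multiplicative gain (lognormal) and additive offset
(normal) — the inter-individual variation that the analysis stage's
within-participant z-scoring is meant to remove. Trial noise can be
calibrated analytically so the planted model R² matches a target.
Reaction times follow the same linear form on a millisecond scale;
trial validity (350–1500 ms, correct response) and the per-participant
minimum-valid-trials rule are applied by the filter operations.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus_stimuli import derive_seed
from .defaults import (
    ACCURACY_MEAN,
    ACCURACY_SD,
    MIN_VALID_TRIALS,
    RT_MAX_MS,
    RT_MIN_MS,
)
from .predictors import PredictorMatrix

__all__ = [
    "ComponentSpec",
    "TrialRecord",
    "ResponseTensor",
    "TimecourseTensor",
    "load_components",
    "calibrate_noise_sd",
    "simulate_predictors_from_correlations",
    "simulate_amplitudes",
    "simulate_timecourses",
    "simulate_behavior",
    "apply_trial_filters",
    "apply_participant_filter",
]

EPOCH_MS = (-200, 800)
SAMPLING_RATE_HZ = 1000
#: Default temporal SD of the evoked bump, ms. Chosen so that less than
#: 1% of the bump's area falls outside a 300-700 ms window for a peak at
#: 400 ms (the widest default window relative to its peak).
DEFAULT_BUMP_SD_MS = 40.0


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: where it peaks, how it is measured, and the
    planted linear effect structure.

    ``betas`` are standardized coefficients (response change in nAm per
    SD of the predictor). ``trial_noise_sd`` may be None, in which case
    :func:`simulate_amplitudes` calibrates it from ``target_r2``.
    """

    name: str
    peak_latency_ms: float
    window_ms: tuple[float, float]
    baseline_nAm: float
    betas: dict[str, float] = field(default_factory=dict)
    trial_noise_sd: float | None = None
    target_r2: float | None = None
    offset_sd: float = 1.0
    gain_sigma: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not (EPOCH_MS[0] <= lo < hi <= EPOCH_MS[1]):
            raise ValueError(f"window {self.window_ms} outside epoch {EPOCH_MS}")
        if (self.trial_noise_sd or 0) < 0 or self.offset_sd < 0 or self.gain_sigma < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass(frozen=True)
class TrialRecord:
    """One lexical-decision trial."""

    participant: int
    item: str
    rt_ms: float
    correct: bool
    is_word: bool = True
    rejected: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError("RT must be positive")
        if self.reason not in (None, "too_fast", "timeout", "incorrect"):
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass
class ResponseTensor:
    """Window amplitudes indexed by (item, participant, component).

    ``values`` has shape (n_items, n_participants, n_components); missing
    trials are NaN, never zero-filled. Units are nAm for raw simulated
    amplitudes and z after within-participant normalization.
    """

    values: np.ndarray
    items: list[str]
    participants: list[int]
    components: list[str]
    units: str = "nAm"

    def __post_init__(self) -> None:
        expected = (len(self.items), len(self.participants), len(self.components))
        if self.values.shape != expected:
            raise ValueError(f"shape {self.values.shape} != {expected}")

    def component_index(self, name: str) -> int:
        return self.components.index(name)

    def to_long(self) -> pd.DataFrame:
        recs = []
        for i, it in enumerate(self.items):
            for s, p in enumerate(self.participants):
                for c, comp in enumerate(self.components):
                    v = self.values[i, s, c]
                    if not np.isnan(v):
                        recs.append((it, p, comp, v))
        return pd.DataFrame(
            recs, columns=["item", "participant", "component", "amplitude"]
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, units: str = "nAm") -> "ResponseTensor":
        items = list(dict.fromkeys(df["item"]))
        participants = sorted(df["participant"].unique())
        components = list(dict.fromkeys(df["component"]))
        values = np.full((len(items), len(participants), len(components)), np.nan)
        ii = {k: v for v, k in enumerate(items)}
        pi = {k: v for v, k in enumerate(participants)}
        ci = {k: v for v, k in enumerate(components)}
        for row in df.itertuples(index=False):
            values[ii[row.item], pi[row.participant], ci[row.component]] = row.amplitude
        return cls(values, items, participants, components, units)


@dataclass
class TimecourseTensor:
    """Time-resolved responses: (item, participant, component, time)."""

    values: np.ndarray
    items: list[str]
    participants: list[int]
    components: list[str]
    times_ms: np.ndarray
    units: str = "nAm"


# ---------------------------------------------------------------------------
# configuration


def load_components(path: str | Path | None = None) -> dict:
    """Load a component/behavior configuration.

    Without a path, the packaged default configuration is used. Returns
    a dict with keys ``components`` (list of :class:`ComponentSpec`),
    ``behavior`` (dict), ``epoch_ms`` and ``sampling_rate_hz``.
    """
    if path is None:
        ref = importlib.resources.files("morphsurprisal").joinpath(
            "data/components.yaml"
        )
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    comps = []
    for name, c in raw["components"].items():
        comps.append(
            ComponentSpec(
                name=name,
                peak_latency_ms=float(c["peak_latency_ms"]),
                window_ms=tuple(float(x) for x in c["window_ms"]),
                baseline_nAm=float(c["baseline_nAm"]),
                betas={k: float(v) for k, v in (c.get("betas") or {}).items()},
                trial_noise_sd=c.get("trial_noise_sd"),
                target_r2=c.get("target_r2"),
                offset_sd=float(c.get("offset_sd", 1.0)),
                gain_sigma=float(c.get("gain_sigma", 0.2)),
            )
        )
    return {
        "components": comps,
        "behavior": raw.get("behavior", {}),
        "epoch_ms": tuple(raw.get("epoch_ms", EPOCH_MS)),
        "sampling_rate_hz": raw.get("sampling_rate_hz", SAMPLING_RATE_HZ),
    }


def calibrate_noise_sd(
    betas: Mapping[str, float],
    target_r2: float,
    corr: pd.DataFrame,
    n_participants: int = 1,
) -> float:
    """Trial-noise SD for which the planted model's population R² equals
    ``target_r2`` on standardized predictors correlated as ``corr``.

    The residual variance satisfying the target at the analysis level is
    sd² = beta' R beta * (1 - R²) / R². Item-level studies report R² on
    responses averaged over participants, which shrinks trial noise by
    sqrt(n_participants); pass ``n_participants`` to obtain the
    *per-trial* SD whose item-average meets the target.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    names = list(betas)
    R = corr.loc[names, names].to_numpy()
    b = np.array([betas[n] for n in names])
    explained = float(b @ R @ b)
    return math.sqrt(explained * (1 - target_r2) / target_r2 * n_participants)


# ---------------------------------------------------------------------------
# generative operations


def simulate_predictors_from_correlations(
    corr: pd.DataFrame | np.ndarray,
    n_items: int,
    seed: int,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw standardized predictor vectors with a given correlation
    structure (zero-mean, unit-variance columns; sample correlations
    converge to ``corr`` as ``n_items`` grows).

    A minimally non-positive-semi-definite matrix (min eigenvalue above
    -1e-8) is repaired by eigenvalue clipping with a warning.
    """
    if isinstance(corr, pd.DataFrame):
        names = list(corr.columns) if names is None else list(names)
        R = corr.to_numpy(dtype=float)
    else:
        R = np.asarray(corr, dtype=float)
        names = [f"x{j}" for j in range(R.shape[0])] if names is None else list(names)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-9):
        raise ValueError("correlation matrix must have unit diagonal")
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {vals.min():.3g})"
        )
    if vals.min() < 0:
        warnings.warn("clipping slightly negative eigenvalues of correlation matrix")
        vals = np.clip(vals, 0, None)
    L = vecs * np.sqrt(vals)
    rng = np.random.default_rng(derive_seed(seed, "predictors-mvn"))
    Z = rng.standard_normal((n_items, R.shape[0]))
    X = Z @ L.T
    return pd.DataFrame(X, columns=names)


def _predictor_frame(X) -> pd.DataFrame:
    if isinstance(X, PredictorMatrix):
        return X.values
    return X


def simulate_amplitudes(
    X,
    components: Sequence[ComponentSpec],
    n_participants: int,
    seed: int,
    corr: pd.DataFrame | None = None,
) -> ResponseTensor:
    """Simulate per-item, per-participant window amplitudes.

    ``X`` is a predictor matrix (PredictorMatrix or DataFrame) whose
    columns cover every beta of every component; masked/NaN cells in a
    referenced column are an error. If a component's ``trial_noise_sd``
    is None it is calibrated from its ``target_r2`` using the empirical
    predictor correlations (or ``corr`` if given). Deterministic given
    ``seed``.
    """
    Xf = _predictor_frame(X)
    n_items = len(Xf)
    values = np.empty((n_items, n_participants, len(components)))
    rng = np.random.default_rng(derive_seed(seed, "amplitudes"))
    for c_idx, comp in enumerate(components):
        for name in comp.betas:
            if name not in Xf.columns:
                raise KeyError(f"component {comp.name}: unknown predictor {name!r}")
            if Xf[name].isna().any():
                raise ValueError(
                    f"component {comp.name}: predictor {name!r} unavailable "
                    "for some items"
                )
        if comp.betas:
            cols = list(comp.betas)
            b = np.array([comp.betas[k] for k in cols])
            signal = Xf[cols].to_numpy() @ b
        else:
            signal = np.zeros(n_items)
        sd = comp.trial_noise_sd
        if sd is None:
            if comp.target_r2 is None:
                sd = 0.0
            else:
                # target_r2 is the item-level R² after cross-participant
                # averaging; inflate per-trial noise accordingly
                use_corr = corr
                if use_corr is None:
                    use_corr = Xf.corr() if comp.betas else None
                sd = calibrate_noise_sd(
                    comp.betas, comp.target_r2, use_corr, n_participants
                )
        gains = rng.lognormal(mean=0.0, sigma=comp.gain_sigma, size=n_participants)
        offsets = rng.normal(0.0, comp.offset_sd, size=n_participants)
        noise = rng.normal(0.0, 1.0, size=(n_items, n_participants)) * sd
        clean = comp.baseline_nAm + signal
        values[:, :, c_idx] = gains[None, :] * (clean[:, None] + noise) + offsets[None, :]
    items = [str(i) for i in Xf.index]
    return ResponseTensor(
        values, items, list(range(n_participants)), [c.name for c in components]
    )


def simulate_timecourses(
    tensor: ResponseTensor,
    components: Sequence[ComponentSpec],
    bump_sd_ms: float = DEFAULT_BUMP_SD_MS,
    epoch_ms: tuple[float, float] = EPOCH_MS,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
) -> TimecourseTensor:
    """Expand window amplitudes into full-epoch time courses.

    Each component contributes a Gaussian bump at its peak latency,
    scaled so that the bump's mean over the component's analysis window
    equals the input amplitude — averaging the trace back over the
    window therefore reproduces the amplitude exactly (zero amplitude
    gives a flat trace).
    """
    dt = 1000.0 / sampling_rate_hz
    times = np.arange(epoch_ms[0], epoch_ms[1], dt)
    by_name = {c.name: c for c in components}
    out = np.zeros(tensor.values.shape + (len(times),))
    for c_idx, name in enumerate(tensor.components):
        comp = by_name[name]
        bump = np.exp(-0.5 * ((times - comp.peak_latency_ms) / bump_sd_ms) ** 2)
        lo, hi = comp.window_ms
        in_win = (times >= lo) & (times < hi)
        bump = bump / bump[in_win].mean()
        amp = tensor.values[:, :, c_idx]
        out[:, :, c_idx, :] = amp[:, :, None] * bump[None, None, :]
    return TimecourseTensor(
        out,
        tensor.items,
        tensor.participants,
        tensor.components,
        times,
        units=tensor.units,
    )


def simulate_behavior(
    X,
    rt_betas: Mapping[str, float],
    rt_baseline_ms: float,
    noise_sd_ms: float,
    accuracy_p: float = ACCURACY_MEAN,
    n_participants: int = 20,
    seed: int = 0,
    accuracy_sd: float = ACCURACY_SD,
    participant_offset_sd_ms: float = 0.0,
    rt_scale_ms: float = 1.0,
    is_word: bool = True,
) -> list[TrialRecord]:
    """Simulate per-trial reaction times and accuracy.

    RT(i, s) = baseline + rt_scale * sum_j beta_j x_ij + offset_s +
    noise, truncated at 1 ms. Correctness is Bernoulli with a
    per-participant probability drawn around ``accuracy_p`` (clipped to
    (0, 1]); accuracy is predictor-independent.
    """
    if not 0 < accuracy_p <= 1:
        raise ValueError("accuracy_p must be in (0, 1]")
    Xf = _predictor_frame(X)
    rng = np.random.default_rng(derive_seed(seed, "behavior"))
    cols = list(rt_betas)
    if cols:
        b = np.array([rt_betas[k] for k in cols])
        signal = Xf[cols].to_numpy() @ b
    else:
        signal = np.zeros(len(Xf))
    p_part = np.clip(
        rng.normal(accuracy_p, accuracy_sd, size=n_participants), 1e-6, 1.0
    )
    offsets = rng.normal(0.0, participant_offset_sd_ms, size=n_participants)
    trials: list[TrialRecord] = []
    items = [str(i) for i in Xf.index]
    for s in range(n_participants):
        noise = rng.normal(0.0, noise_sd_ms, size=len(items))
        correct = rng.random(len(items)) < p_part[s]
        for i, item in enumerate(items):
            rt = rt_baseline_ms + rt_scale_ms * signal[i] + offsets[s] + noise[i]
            trials.append(
                TrialRecord(
                    participant=s,
                    item=item,
                    rt_ms=max(rt, 1.0),
                    correct=bool(correct[i]),
                    is_word=is_word,
                )
            )
    return trials


# ---------------------------------------------------------------------------
# validity filters


def apply_trial_filters(
    trials: Sequence[TrialRecord],
    min_rt_ms: float = RT_MIN_MS,
    max_rt_ms: float = RT_MAX_MS,
) -> tuple[list[TrialRecord], Counter]:
    """Keep correct trials with min_rt <= RT <= max_rt.

    Returns the kept trials and a per-reason rejection count
    (incorrect / too_fast / timeout). Idempotent: re-filtering the kept
    trials rejects nothing.
    """
    kept: list[TrialRecord] = []
    log: Counter = Counter()
    for t in trials:
        if not t.correct:
            log["incorrect"] += 1
        elif t.rt_ms < min_rt_ms:
            log["too_fast"] += 1
        elif t.rt_ms > max_rt_ms:
            log["timeout"] += 1
        else:
            kept.append(t)
            continue
    return kept, log


def apply_participant_filter(
    trials: Sequence[TrialRecord],
    min_valid: int = MIN_VALID_TRIALS,
    total: int = 360,
) -> tuple[set[int], dict[int, int]]:
    """Retain participants with at least ``min_valid`` valid word trials.

    ``trials`` should be the word trials of the experiment; a trial is
    valid if it passes :func:`apply_trial_filters`. Returns the retained
    participant set and the per-participant valid-trial counts.
    """
    kept, _ = apply_trial_filters(trials)
    counts: Counter = Counter()
    participants = {t.participant for t in trials}
    for t in kept:
        counts[t.participant] += 1
    retained = {p for p in participants if counts[p] >= min_valid}
    return retained, {p: counts[p] for p in sorted(participants)}
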