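"""Item-level analysis: z-scoring, averaging, correlation, stepwise fit.

Mirrors the analysis stage of an item-level evoked-response study:
window amplitudes are normalized to z-scores within each participant
(removing individual gain and offset), averaged across participants per
item, and regressed on the predictor variables — first one predictor at
a time (Pearson r with an F(1, n-2) significance test), then by forward
stepwise multiple regression with a partial-F entry criterion and
standardized coefficients. Tertile binning of time-resolved responses
supports the grand-average visualizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .predictors import PSEUDOWORD_COLUMNS, PredictorMatrix
from .synth_responses import (
    ResponseTensor,
    TimecourseTensor,
    TrialRecord,
    apply_participant_filter,
    apply_trial_filters,
)

__all__ = [
    "ItemResponseMatrix",
    "RegressionReport",
    "window_average",
    "zscore_within_participant",
    "average_across_items",
    "simple_correlations",
    "forward_stepwise",
    "bin_by_predictor",
    "analyze",
]


@dataclass
class ItemResponseMatrix:
    """Cross-participant mean z-scores per item and component."""

    means: pd.DataFrame  # items x components
    n_participants: pd.DataFrame  # contributing participants per cell


@dataclass
class RegressionReport:
    """Simple-correlation table plus the stepwise model for one target."""

    target: str
    simple: pd.DataFrame  # index predictor; columns r, F, p, stars
    selected: list[str]
    betas: dict[str, float]
    r2: float
    model_f: float
    model_df: tuple[int, int]
    model_p: float
    steps: list[dict] = field(default_factory=list)


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def window_average(
    timecourses: TimecourseTensor, window_ms: tuple[float, float]
) -> ResponseTensor:
    """Mean amplitude over a time window, start-inclusive, end-exclusive."""
    lo, hi = window_ms
    t = timecourses.times_ms
    if lo < t[0] or hi > t[-1] + (t[1] - t[0]):
        raise ValueError(f"window {window_ms} outside epoch [{t[0]}, {t[-1]}]")
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    values = timecourses.values[:, :, :, mask].mean(axis=3)
    return ResponseTensor(
        values,
        timecourses.items,
        timecourses.participants,
        timecourses.components,
        units=timecourses.units,
    )


def zscore_within_participant(tensor: ResponseTensor) -> ResponseTensor:
    """Standardize each participant x component column over items.

    Uses the n-1 SD; invariant under per-participant affine transforms
    (which is the point: individual gain and offset drop out). Missing
    items are ignored in the mean/SD and stay missing. A zero-variance
    column is an error naming the participant and component.
    """
    v = tensor.values
    out = np.full_like(v, np.nan)
    for s, part in enumerate(tensor.participants):
        for c, comp in enumerate(tensor.components):
            col = v[:, s, c]
            obs = ~np.isnan(col)
            if obs.sum() < 2:
                raise ValueError(
                    f"participant {part}, component {comp}: "
                    "need at least 2 items to z-score"
                )
            sd = np.std(col[obs], ddof=1)
            if sd == 0:
                raise ValueError(
                    f"participant {part}, component {comp}: zero variance"
                )
            out[obs, s, c] = (col[obs] - col[obs].mean()) / sd
    return ResponseTensor(
        out, tensor.items, tensor.participants, tensor.components, units="z"
    )


def average_across_items(tensor: ResponseTensor) -> ItemResponseMatrix:
    """Average each item's response over the participants that have it.

    Missing trials are excluded from the mean, never zero-filled; an
    item with no data in some component is an error.
    """
    v = tensor.values
    n = (~np.isnan(v)).sum(axis=1)
    if (n == 0).any():
        bad = [tensor.items[i] for i in np.where((n == 0).any(axis=1))[0][:5]]
        raise ValueError(f"items with no data: {bad}")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(v, axis=1)
    return ItemResponseMatrix(
        means=pd.DataFrame(means, index=tensor.items, columns=tensor.components),
        n_participants=pd.DataFrame(
            n, index=tensor.items, columns=tensor.components
        ),
    )


# ---------------------------------------------------------------------------
# statistics


def _columns_for(X) -> pd.DataFrame:
    """Predictor columns usable for analysis (fully observed)."""
    if isinstance(X, PredictorMatrix):
        return X.values[X.available_columns()]
    return X.dropna(axis=1)


def simple_correlations(X, y: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-predictor Pearson r with F = r²(n-2)/(1-r²) on (1, n-2) df.

    Masked (partially unavailable) predictor columns are skipped.
    """
    Xf = _columns_for(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 3:
        raise ValueError("need at least 3 items")
    if len(Xf) != n:
        raise ValueError("predictor and response lengths differ")
    rows = {}
    for col in Xf.columns:
        x = Xf[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"zero-variance predictor column {col!r}")
        r, _ = stats.pearsonr(x, yv)
        f = r**2 * (n - 2) / (1 - r**2) if abs(r) < 1 else np.inf
        p = stats.f.sf(f, 1, n - 2)
        rows[col] = {"r": r, "F": f, "p": p, "stars": _stars(p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "predictor"
    return out


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def _ols_r2(Xz: np.ndarray, yz: np.ndarray, cols: list[int]) -> tuple[float, np.ndarray]:
    A = Xz[:, cols]
    beta, *_ = np.linalg.lstsq(A, yz, rcond=None)
    resid = yz - A @ beta
    return 1.0 - resid @ resid / (yz @ yz), beta


def forward_stepwise(X, y, alpha: float = 0.05) -> RegressionReport:
    """Forward stepwise multiple regression with a partial-F entry test.

    Predictors and response are z-scored internally, so the reported
    coefficients are standardized. At each step the candidate giving the
    largest R² increase enters if its partial-F p-value is below
    ``alpha`` (ties broken by column order); selection stops otherwise.
    """
    Xf = _columns_for(X)
    names = list(Xf.columns)
    Xz = _standardize(Xf.to_numpy(dtype=float))
    yv = np.asarray(y, dtype=float)
    yz = (yv - yv.mean()) / yv.std(ddof=1)
    n = len(yz)
    selected: list[int] = []
    r2 = 0.0
    steps: list[dict] = []
    while len(selected) < len(names):
        best = None
        for j in range(len(names)):
            if j in selected:
                continue
            r2_new, _ = _ols_r2(Xz, yz, selected + [j])
            if best is None or r2_new > best[0] + 1e-12:
                best = (r2_new, j)
        r2_new, j = best
        if r2_new - r2 <= 1e-12:  # no candidate improves the fit
            break
        k = len(selected) + 1
        df2 = n - k - 1
        if 1 - r2_new <= 1e-15:
            partial_f, p = np.inf, 0.0
        else:
            partial_f = (r2_new - r2) * df2 / (1 - r2_new)
            p = stats.f.sf(partial_f, 1, df2)
        if p >= alpha:
            break
        selected.append(j)
        steps.append(
            {"predictor": names[j], "r2": r2_new, "partial_F": partial_f, "p": p}
        )
        r2 = r2_new
    if selected:
        A = Xz[:, selected]
        if np.linalg.cond(A.T @ A) > 1e8:
            raise ValueError("selected predictors are collinear")
        r2, beta = _ols_r2(Xz, yz, selected)
        k = len(selected)
        model_f = (r2 / k) / ((1 - r2) / (n - k - 1)) if r2 < 1 else np.inf
        model_p = stats.f.sf(model_f, k, n - k - 1)
        betas = {names[j]: float(b) for j, b in zip(selected, beta)}
        df = (k, n - k - 1)
    else:
        betas, model_f, model_p, df, r2 = {}, 0.0, 1.0, (0, n - 1), 0.0
    return RegressionReport(
        target="",
        simple=simple_correlations(Xf, yv),
        selected=[names[j] for j in selected],
        betas=betas,
        r2=float(r2),
        model_f=float(model_f),
        model_df=df,
        model_p=float(model_p),
        steps=steps,
    )


def bin_by_predictor(
    predictor: pd.Series,
    curves: TimecourseTensor,
    component: str,
    bin_size: int = 60,
) -> pd.DataFrame:
    """Grand-average curves for the lowest, median-centered, and highest
    ``bin_size`` items ranked by the predictor.

    Returns a DataFrame indexed by time (ms) with columns low, mid,
    high; the three bins are disjoint. Ties are broken by item order.
    """
    items = list(curves.items)
    if len(items) < 3 * bin_size:
        raise ValueError(
            f"need at least {3 * bin_size} items for bins of {bin_size}"
        )
    vals = predictor.loc[items].to_numpy(dtype=float)
    order = np.argsort(vals, kind="stable")
    n = len(items)
    low = order[:bin_size]
    high = order[-bin_size:]
    mid_start = (n - bin_size) // 2
    mid = order[mid_start : mid_start + bin_size]
    c = curves.components.index(component)
    out = {}
    for name, idx in (("low", low), ("mid", mid), ("high", high)):
        with np.errstate(invalid="ignore"):
            out[name] = np.nanmean(curves.values[idx, :, c, :], axis=(0, 1))
    return pd.DataFrame(out, index=pd.Index(curves.times_ms, name="time_ms"))


# ---------------------------------------------------------------------------
# end-to-end analysis


def _load_predictors(source) -> PredictorMatrix:
    if isinstance(source, PredictorMatrix):
        return source
    return PredictorMatrix.from_tsv(source)


def _load_df(source, columns) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    df = pd.read_csv(source, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"schema mismatch: missing columns {sorted(missing)}")
    return df


def analyze(
    predictors,
    amplitudes,
    trials,
    config: Mapping | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, dict[str, RegressionReport]]:
    """Run the full item-level analysis.

    Inputs may be in-memory objects or TSV paths: a predictor matrix
    (items x predictors, NA = unavailable), long-format amplitudes
    (item, participant, component, amplitude), and trials (participant,
    item, rt_ms, correct). Word and pseudoword items (distinguished by
    surface-frequency availability) are analyzed separately, pseudowords
    with their four available predictors. Pipeline per class: trial
    validity filters -> participant filter (word trials) -> RT item
    means -> within-participant z-scoring -> cross-participant item
    averaging -> simple correlations and forward stepwise regression for
    each component and for RT. Returns reports[item_class][target];
    optionally writes simple_correlations.tsv and stepwise.tsv.
    """
    cfg = dict(config or {})
    alpha = cfg.get("alpha", 0.05)
    min_rt = cfg.get("min_rt_ms", 350.0)
    max_rt = cfg.get("max_rt_ms", 1500.0)
    min_valid = cfg.get("min_valid_trials")

    pm = _load_predictors(predictors)
    amp = _load_df(amplitudes, ["item", "participant", "component", "amplitude"])
    amp = amp.astype({"item": str})
    tri = _load_df(trials, ["participant", "item", "rt_ms", "correct"])
    tri = tri.astype({"item": str})

    word_mask = pm.available["surface_surprisal_bits"]
    classes = {}
    if word_mask.any():
        classes["words"] = [str(i) for i in pm.values.index[word_mask]]
    if (~word_mask).any():
        classes["pseudowords"] = [str(i) for i in pm.values.index[~word_mask]]

    records = [
        TrialRecord(
            participant=int(r.participant),
            item=str(r.item),
            rt_ms=float(r.rt_ms),
            correct=bool(r.correct),
        )
        for r in tri.itertuples(index=False)
    ]
    word_items = set(classes.get("words", []))
    word_trials = [t for t in records if t.item in word_items]
    if min_valid is None:
        # the 290-of-360 validity rule, scaled to the word-set size
        min_valid = round(290 / 360 * len(word_items)) if word_items else 0
    if word_trials:
        retained, _ = apply_participant_filter(
            word_trials, min_valid=min_valid, total=len(word_items)
        )
    else:
        retained = {t.participant for t in records}

    reports: dict[str, dict[str, RegressionReport]] = {}
    simple_rows, step_rows = [], []
    for cls, items in classes.items():
        item_set = set(items)
        sub = pm.values.loc[[i for i in pm.values.index if str(i) in item_set]]
        sub_avail = pm.available.loc[sub.index]
        sub_pm = PredictorMatrix(sub, sub_avail)
        cols = (
            list(PSEUDOWORD_COLUMNS)
            if cls == "pseudowords"
            else sub_pm.available_columns()
        )
        Xcls = sub_pm.values[cols]

        cls_trials = [
            t for t in records if t.item in item_set and t.participant in retained
        ]
        kept, _ = apply_trial_filters(cls_trials, min_rt, max_rt)
        rt_df = pd.DataFrame(
            [(t.item, t.rt_ms) for t in kept], columns=["item", "rt_ms"]
        )
        rt_means = rt_df.groupby("item")["rt_ms"].mean()

        amp_cls = amp[amp["item"].isin(item_set) & amp["participant"].isin(retained)]
        targets: dict[str, pd.Series] = {}
        if not amp_cls.empty:
            tensor = ResponseTensor.from_long(amp_cls)
            z = zscore_within_participant(tensor)
            irm = average_across_items(z)
            for comp in irm.means.columns:
                targets[comp] = irm.means[comp]
        if not rt_means.empty:
            targets["reaction_time"] = rt_means

        reports[cls] = {}
        for target, y in targets.items():
            common = [i for i in Xcls.index if str(i) in set(y.index.astype(str))]
            Xt = Xcls.loc[common]
            yt = y.loc[[str(i) for i in common]]
            rep = forward_stepwise(Xt, yt.to_numpy(), alpha=alpha)
            rep.target = target
            reports[cls][target] = rep
            for pred, row in rep.simple.iterrows():
                simple_rows.append(
                    {"class": cls, "target": target, "predictor": pred, **row}
                )
            for step_i, (pred, beta) in enumerate(rep.betas.items(), start=1):
                step_rows.append(
                    {
                        "class": cls,
                        "target": target,
                        "predictor": pred,
                        "beta": beta,
                        "step": rep.selected.index(pred) + 1,
                        "r2": rep.r2,
                        "F": rep.model_f,
                    }
                )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(simple_rows).to_csv(
            out / "simple_correlations.tsv", sep="\t", index=False
        )
        pd.DataFrame(step_rows).to_csv(out / "stepwise.tsv", sep="\t", index=False)
    return reports
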