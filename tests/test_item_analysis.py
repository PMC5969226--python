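"""Analysis stage: z-scoring, averaging, correlations, stepwise, bins."""

import numpy as np
import pandas as pd
import pytest

from morphsurprisal import item_analysis as IA
from morphsurprisal import synth_responses as S


def tensor_from(values, items=None, participants=None, components=("c",)):
    v = np.asarray(values, dtype=float)
    items = items or [f"w{i}" for i in range(v.shape[0])]
    participants = participants or list(range(v.shape[1]))
    return S.ResponseTensor(v, items, participants, list(components))


class TestWindowAverage:
    def test_constant_trace(self):
        comp = S.ComponentSpec("c", 100, (80, 120), 0.0)
        times = np.arange(-200, 800, 1.0)
        vals = np.full((2, 2, 1, len(times)), 3.25)
        tc = S.TimecourseTensor(vals, ["a", "b"], [0, 1], ["c"], times)
        out = IA.window_average(tc, (80, 120))
        np.testing.assert_allclose(out.values, 3.25)

    def test_linear_ramp_halfway(self):
        times = np.arange(0.0, 100.0, 1.0)
        ramp = np.linspace(0, 1, len(times))
        vals = ramp[None, None, None, :]
        tc = S.TimecourseTensor(vals, ["a"], [0], ["c"], times)
        out = IA.window_average(tc, (0, 100))
        assert out.values[0, 0, 0] == pytest.approx(0.5, abs=1 / len(times))

    def test_window_outside_epoch_rejected(self):
        times = np.arange(-200.0, 800.0, 1.0)
        tc = S.TimecourseTensor(np.zeros((1, 1, 1, len(times))), ["a"], [0],
                                ["c"], times)
        with pytest.raises(ValueError):
            IA.window_average(tc, (700, 900))


class TestZScore:
    def test_three_point_example(self):
        t = tensor_from(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        z = IA.zscore_within_participant(t)
        np.testing.assert_allclose(z.values[:, 0, 0], [-1.0, 0.0, 1.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((20, 4, 2))
        t = tensor_from(v, components=["c1", "c2"])
        z1 = IA.zscore_within_participant(t)
        scaled = v * np.array([2.0, 1.5, 0.3, 7.0])[None, :, None] + 5.0
        z2 = IA.zscore_within_participant(tensor_from(scaled, components=["c1", "c2"]))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-12)

    def test_zero_variance_named_error(self):
        t = tensor_from(np.ones((5, 2, 1)))
        with pytest.raises(ValueError, match="participant 0"):
            IA.zscore_within_participant(t)

    def test_gain_offset_corruption_recovered(self):
        # per-participant gain/offset on a noise-free signal: the item
        # profile after z-scoring matches the clean signal profile
        rng = np.random.default_rng(1)
        signal = rng.standard_normal(50)
        gains = rng.lognormal(0, 0.3, size=8)
        offsets = rng.normal(0, 2.0, size=8)
        v = gains[None, :] * signal[:, None] + offsets[None, :]
        z = IA.zscore_within_participant(tensor_from(v[:, :, None]))
        item_mean = z.values[:, :, 0].mean(axis=1)
        r = np.corrcoef(item_mean, signal)[0, 1]
        assert r > 0.99


class TestAverageAcrossItems:
    def test_single_participant_identity(self):
        v = np.arange(6, dtype=float).reshape(6, 1, 1)
        out = IA.average_across_items(tensor_from(v))
        np.testing.assert_allclose(out.means["c"].to_numpy(), v[:, 0, 0])
        assert (out.n_participants["c"] == 1).all()

    def test_missing_excluded_not_zero_filled(self):
        v = np.array([[1.0, np.nan], [2.0, 4.0]]).reshape(2, 2, 1)
        out = IA.average_across_items(tensor_from(v))
        assert out.means["c"].iloc[0] == pytest.approx(1.0)
        assert out.means["c"].iloc[1] == pytest.approx(3.0)
        assert out.n_participants["c"].tolist() == [1, 2]

    def test_noise_variance_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        for n in (4, 16):
            v = rng.standard_normal((2000, n, 1))
            out = IA.average_across_items(tensor_from(v))
            var = out.means["c"].var()
            assert var == pytest.approx(1 / n, rel=0.15)


class TestSimpleCorrelations:
    def test_self_correlation_is_one(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"p": x})
        out = IA.simple_correlations(X, x)
        assert out.loc["p", "r"] == pytest.approx(1.0)

    def test_df_at_study_size(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"p": rng.standard_normal(360)})
        y = rng.standard_normal(360)
        out = IA.simple_correlations(X, y)
        r = out.loc["p", "r"]
        # F computed on (1, 358) df
        assert out.loc["p", "F"] == pytest.approx(r**2 * 358 / (1 - r**2))

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"p": rng.standard_normal(100)})
        y = rng.standard_normal(100)
        out = IA.simple_correlations(X, y)
        x = X["p"].to_numpy()
        r_oracle = ((x - x.mean()) @ (y - y.mean())) / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out.loc["p", "r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        X = pd.DataFrame({"p": np.ones(10)})
        with pytest.raises(ValueError):
            IA.simple_correlations(X, np.arange(10.0))


class TestForwardStepwise:
    def test_exact_predictor_one_step(self):
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(100)
        X = pd.DataFrame({"x1": x1, "x2": rng.standard_normal(100)})
        rep = IA.forward_stepwise(X, x1)
        assert rep.selected == ["x1"]
        assert rep.betas["x1"] == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_duplicate_column_enters_once(self):
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal(200)
        X = pd.DataFrame({"x1": x1, "x2": x1.copy()})
        y = x1 + rng.normal(0, 0.5, 200)
        rep = IA.forward_stepwise(X, y)
        assert rep.selected == ["x1"]

    def test_true_predictor_found_reliably(self):
        hits = 0
        for rep_i in range(100):
            rng = np.random.default_rng(1000 + rep_i)
            X = pd.DataFrame(
                rng.standard_normal((360, 4)), columns=list("abcd")
            )
            y = 0.5 * X["b"].to_numpy() + rng.normal(0, 1.0, 360)
            rep = IA.forward_stepwise(X, y)
            if rep.selected and rep.selected[0] == "b":
                hits += 1
        assert hits >= 95

    def test_null_selects_nothing_mostly(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((360, 3)), columns=list("abc"))
        y = rng.standard_normal(360)
        rep = IA.forward_stepwise(X, y, alpha=1e-9)
        assert rep.selected == []
        assert rep.r2 == 0.0


class TestBins:
    def test_disjoint_bins_of_sixty(self):
        rng = np.random.default_rng(0)
        n = 360
        items = [f"w{i}" for i in range(n)]
        pred = pd.Series(rng.standard_normal(n), index=items)
        times = np.arange(-200.0, 800.0, 10.0)
        vals = rng.standard_normal((n, 3, 1, len(times)))
        tc = S.TimecourseTensor(vals, items, [0, 1, 2], ["c"], times)
        curves = IA.bin_by_predictor(pred, tc, "c", bin_size=60)
        assert curves.shape == (len(times), 3)
        assert list(curves.columns) == ["low", "mid", "high"]

    def test_planted_effect_orders_bins(self):
        rng = np.random.default_rng(2)
        n = 360
        items = [f"w{i}" for i in range(n)]
        pred = pd.Series(rng.standard_normal(n), index=items)
        comp = S.ComponentSpec(
            "c", 100, (80, 120), 0.0, betas={"p": 1.0},
            trial_noise_sd=0.5, offset_sd=0.0, gain_sigma=0.0,
        )
        X = pd.DataFrame({"p": pred.to_numpy()}, index=items)
        t = S.simulate_amplitudes(X, [comp], 10, seed=3)
        tc = S.simulate_timecourses(t, [comp])
        curves = IA.bin_by_predictor(pred, tc, "c", bin_size=60)
        win = (tc.times_ms >= 80) & (tc.times_ms < 120)
        assert curves["high"][win].mean() > curves["low"][win].mean()

    def test_too_few_items_rejected(self):
        items = [f"w{i}" for i in range(100)]
        pred = pd.Series(np.arange(100.0), index=items)
        times = np.arange(0.0, 10.0, 1.0)
        tc = S.TimecourseTensor(
            np.zeros((100, 1, 1, len(times))), items, [0], ["c"], times
        )
        with pytest.raises(ValueError):
            IA.bin_by_predictor(pred, tc, "c", bin_size=60)


@pytest.fixture(scope="module")
def dataset():
    from morphsurprisal.defaults import DEFAULT_PREDICTOR_CORRELATIONS
    from morphsurprisal.predictors import PredictorMatrix

    n = 120
    X = S.simulate_predictors_from_correlations(
        DEFAULT_PREDICTOR_CORRELATIONS, n, seed=21
    )
    X.index = [f"w{i}" for i in range(n)]
    avail = pd.DataFrame(True, index=X.index, columns=X.columns)
    pm = PredictorMatrix(X, avail)
    cfg = S.load_components()
    tensor = S.simulate_amplitudes(X, cfg["components"], 8, seed=22)
    beh = cfg["behavior"]
    noise = 95.0 * S.calibrate_noise_sd(
        beh["rt_betas"], beh["target_r2"], X.corr(), n_participants=8
    )
    trials = S.simulate_behavior(
        X, beh["rt_betas"], 852.0, noise, n_participants=8, seed=23,
        rt_scale_ms=95.0,
    )
    tri = pd.DataFrame(
        [(t.participant, t.item, t.rt_ms, int(t.correct)) for t in trials],
        columns=["participant", "item", "rt_ms", "correct"],
    )
    return pm, tensor.to_long(), tri


class TestAnalyzeEndToEnd:
    def test_deterministic_outputs(self, dataset, tmp_path):
        pm, amp, tri = dataset
        cfg = {"min_valid_trials": 90}
        IA.analyze(pm, amp, tri, config=cfg, out_dir=tmp_path / "a")
        IA.analyze(pm, amp, tri, config=cfg, out_dir=tmp_path / "b")
        for name in ("simple_correlations.tsv", "stepwise.tsv"):
            assert (tmp_path / "a" / name).read_text() == (
                tmp_path / "b" / name
            ).read_text()

    def test_reports_cover_all_targets(self, dataset):
        pm, amp, tri = dataset
        reports = IA.analyze(pm, amp, tri, config={"min_valid_trials": 90})
        assert set(reports) == {"words"}
        assert set(reports["words"]) == {
            "occipital", "occipito_temporal", "left_temporal",
            "right_temporal", "reaction_time",
        }
        for rep in reports["words"].values():
            assert 0.0 <= rep.r2 <= 1.0

    def test_pseudowords_use_four_predictors(self):
        from morphsurprisal.predictors import (
            PSEUDOWORD_COLUMNS,
            PREDICTOR_COLUMNS,
            PredictorMatrix,
        )

        n = 60
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(
            rng.standard_normal((n, 7)),
            columns=list(PREDICTOR_COLUMNS),
            index=[f"p{i}" for i in range(n)],
        )
        avail = pd.DataFrame(False, index=vals.index, columns=vals.columns)
        for c in PSEUDOWORD_COLUMNS:
            avail[c] = True
        pm = PredictorMatrix(vals, avail)
        trials = [
            S.TrialRecord(p, f"p{i}", float(600 + 10 * rng.random()), True)
            for p in range(4)
            for i in range(n)
        ]
        tri = pd.DataFrame(
            [(t.participant, t.item, t.rt_ms, int(t.correct)) for t in trials],
            columns=["participant", "item", "rt_ms", "correct"],
        )
        amp = pd.DataFrame(columns=["item", "participant", "component", "amplitude"])
        reports = IA.analyze(pm, amp, tri, config={"min_valid_trials": 1})
        rep = reports["pseudowords"]["reaction_time"]
        assert set(rep.simple.index) == set(PSEUDOWORD_COLUMNS)
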