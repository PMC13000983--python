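"""Psychometric model and behavioral-analysis tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from prioshift.behavior import (
    PsychometricModel,
    PsychometricParams,
    distance_effect,
    fit_psychometric,
    psychometric_predict,
    residualize,
    switch_cost_summary,
)
from prioshift.circstats import fold_offset
from prioshift.synth import (
    ORIENTATION_GRID,
    PROBE_GRID,
    RTModel,
    TaskConfig,
    generate_task,
    simulate_responses,
)


def _simulate_offsets(rng, n):
    c = rng.choice(ORIENTATION_GRID, n)
    u = rng.choice(ORIENTATION_GRID, n)
    pr = rng.choice(PROBE_GRID, n)
    return fold_offset(pr - c), fold_offset(pr - u)


class TestPredict:
    def test_zero_offset_gives_half(self):
        p = psychometric_predict(0.0, None, PsychometricParams(lapse=0.0, sigma=22.0))
        assert p == pytest.approx(0.5)

    def test_far_offset_saturates(self):
        p = psychometric_predict(60.0, None, PsychometricParams(lapse=0.0, sigma=10.0))
        assert p == pytest.approx(norm.cdf(6.0), abs=1e-12)

    def test_swap_model_matches_normal_cdf_oracle(self):
        # independent evaluation: 0.7 Phi(2) + 0.3 Phi(-2)
        params = PsychometricParams(lapse=0.0, sigma=15.0, p_swap=0.3)
        p = psychometric_predict(30.0, -30.0, params)
        assert p == pytest.approx(0.7 * norm.cdf(2.0) + 0.3 * norm.cdf(-2.0), abs=1e-12)

    def test_printed_form_asymptotes_are_asymmetric(self):
        params = PsychometricParams(lapse=0.1, sigma=5.0)
        lo = psychometric_predict(-90.0 + 1e-9, None, params)
        hi = psychometric_predict(90.0, None, params)
        assert lo == pytest.approx(0.1, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_variant_asymptotes(self):
        params = PsychometricParams(lapse=0.1, sigma=5.0)
        lo = psychometric_predict(-90.0 + 1e-9, None, params, symmetric_lapse=True)
        hi = psychometric_predict(90.0, None, params, symmetric_lapse=True)
        assert lo == pytest.approx(0.1, abs=1e-6)
        assert hi == pytest.approx(0.9, abs=1e-6)

    @given(st.floats(-89.99, 90.0), st.floats(-89.99, 90.0),
           st.floats(0.0, 0.4), st.floats(2.0, 60.0))
    def test_monotone_in_cued_offset(self, th1, th2, lapse, sigma):
        params = PsychometricParams(lapse=lapse, sigma=sigma)
        lo, hi = sorted([th1, th2])
        p_lo = psychometric_predict(lo, None, params, symmetric_lapse=True)
        p_hi = psychometric_predict(hi, None, params, symmetric_lapse=True)
        assert p_lo <= p_hi + 1e-12
        assert 0.0 <= p_lo <= 1.0

    def test_out_of_fold_offsets_rejected(self):
        with pytest.raises(ValueError, match="folded"):
            psychometric_predict(120.0, None, PsychometricParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            psychometric_predict(0.0, None, PsychometricParams(lapse=0.7, p_swap=0.7))
        with pytest.raises(ValueError):
            psychometric_predict(0.0, None, PsychometricParams(sigma=-1.0))


class TestFit:
    def test_parameter_recovery_basic(self):
        rng = np.random.default_rng(0)
        thc, _ = _simulate_offsets(rng, 10_000)
        truth = PsychometricParams(lapse=0.07, sigma=17.6)
        y = rng.random(10_000) < psychometric_predict(thc, None, truth)
        m = PsychometricModel().fit(thc[:, None], y)
        # tolerance: ~3x the Monte-Carlo SD of each estimator at this n
        assert m.lapse_ == pytest.approx(0.07, abs=0.02)
        assert m.sigma_ == pytest.approx(17.6, abs=2.0)
        assert m.converged_

    def test_fitted_likelihood_at_least_as_good_as_truth(self):
        rng = np.random.default_rng(1)
        thc, _ = _simulate_offsets(rng, 4000)
        truth = PsychometricParams(lapse=0.1, sigma=20.0)
        y = rng.random(4000) < psychometric_predict(thc, None, truth)
        m = PsychometricModel().fit(thc[:, None], y)
        p_true = np.clip(psychometric_predict(thc, None, truth), 1e-12, 1 - 1e-12)
        nll_true = -np.sum(np.where(y, np.log(p_true), np.log1p(-p_true)))
        assert m.nll_ <= nll_true + 1e-6

    def test_swap_free_data_fits_zero_swap_and_nested_nll(self):
        rng = np.random.default_rng(2)
        thc, thu = _simulate_offsets(rng, 8000)
        truth = PsychometricParams(lapse=0.05, sigma=18.0, p_swap=0.0)
        y = rng.random(8000) < psychometric_predict(thc, thu, truth)
        X = np.column_stack([thc, thu])
        basic = PsychometricModel().fit(X, y)
        swap = PsychometricModel(include_swap=True).fit(X, y)
        assert swap.p_swap_ < 0.02
        assert swap.nll_ <= basic.nll_ + 1e-6          # freeing p_swap never hurts
        assert swap.nll_ >= basic.nll_ - 3.0           # ... and gains little here

    def test_degenerate_all_one_response_flagged(self):
        rng = np.random.default_rng(3)
        thc, _ = _simulate_offsets(rng, 500)
        m = PsychometricModel().fit(thc[:, None], np.ones(500, dtype=bool))
        assert m.boundary_

    def test_fit_psychometric_requires_min_trials(self):
        trials = generate_task(TaskConfig(n_blocks=2), seed=4)
        trials = simulate_responses(trials, seed=5)
        with pytest.raises(ValueError, match="at least"):
            fit_psychometric(trials, condition_filter="switch", min_trials=50)


class TestSwitchCosts:
    def _multi_participant(self, n=6, seed=0, rt_model=None, params=None):
        rows = []
        for p in range(n):
            t = generate_task(TaskConfig(n_blocks=16), seed=seed + p)
            t = simulate_responses(t, params_by_condition=params, rt_model=rt_model,
                                   seed=1000 + seed + p)
            t["participant"] = p
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def test_planted_rt_cost_recovered(self):
        slow = RTModel(intercept_ms={"switch": 480.0, "repeat1": 400.0,
                                     "repeat2plus": 400.0, "block_start": 400.0},
                       slope_ms_per_deg={c: 0.0 for c in
                                         ["switch", "repeat1", "repeat2plus", "block_start"]})
        df = self._multi_participant(rt_model=slow, seed=10)
        res = switch_cost_summary(df)
        row = res["tests"].query("measure == 'median_rt_ms' and contrast == 'switch-repeat1'")
        assert row["mean_diff"].iloc[0] == pytest.approx(80.0, abs=15.0)
        assert row["t"].iloc[0] > 3

    def test_identical_conditions_give_null_contrast(self):
        same = {c: PsychometricParams(lapse=0.08, sigma=18.0)
                for c in ["switch", "repeat1", "repeat2plus", "block_start"]}
        df = self._multi_participant(params=same, seed=20)
        res = switch_cost_summary(df)
        row = res["tests"].query("measure == 'accuracy' and contrast == 'switch-repeat1'")
        assert abs(row["t"].iloc[0]) < 3.0

    def test_single_condition_rejected(self):
        df = self._multi_participant(n=2, seed=30)
        only_switch = df[df["condition"] == "switch"]
        with pytest.raises(ValueError):
            switch_cost_summary(only_switch)


class TestDistanceEffect:
    def test_planted_rt_distance_slope_recovered(self):
        rt = RTModel(slope_ms_per_deg={"switch": 2.0, "repeat1": 0.5,
                                       "repeat2plus": 0.5, "block_start": 0.5})
        rows = []
        for p in range(6):
            t = generate_task(TaskConfig(n_blocks=32), seed=40 + p)
            t = simulate_responses(t, rt_model=rt, seed=140 + p)
            t["participant"] = p
            rows.append(t)
        df = pd.concat(rows, ignore_index=True)
        de = distance_effect(df, outcome="rt")
        wide = de["slopes"].pivot(index="participant", columns="condition",
                                  values="slope_per_10deg")
        assert wide["switch"].mean() == pytest.approx(20.0, abs=4.0)
        assert wide["repeat"].mean() == pytest.approx(5.0, abs=3.0)
        paired = de["tests"].query("contrast == 'switch-repeat'")
        assert paired["t"].iloc[0] > 3

    def test_swap_errors_induce_accuracy_distance_slope_on_switch(self):
        # accuracy falls with item distance when swaps occur: a swapped
        # comparison misleads more, the farther apart the two items are
        params = {"switch": PsychometricParams(lapse=0.02, sigma=15.0, p_swap=0.25),
                  **{c: PsychometricParams(lapse=0.02, sigma=15.0, p_swap=0.0)
                     for c in ["repeat1", "repeat2plus", "block_start"]}}
        rows = []
        for p in range(6):
            t = generate_task(TaskConfig(n_blocks=32), seed=60 + p)
            t = simulate_responses(t, params_by_condition=params, seed=160 + p)
            t["participant"] = p
            rows.append(t)
        de = distance_effect(pd.concat(rows, ignore_index=True), outcome="accuracy")
        wide = de["slopes"].pivot(index="participant", columns="condition",
                                  values="slope_per_10deg")
        # accuracy is a proportion: expect > 1 percentage point lost per 10 deg
        assert wide["switch"].mean() < -0.01
        assert abs(wide["repeat"].mean()) < 0.01

    def test_constant_distance_rejected(self):
        t = generate_task(TaskConfig(n_blocks=16), seed=70)
        t = simulate_responses(t, seed=71)
        t = t[np.isclose(t["item_distance"], t["item_distance"].iloc[0])]
        with pytest.raises(ValueError):
            distance_effect(t)


class TestResidualize:
    def test_exact_fit_gives_zero_residuals(self):
        x = np.linspace(0, 1, 50)
        assert np.allclose(residualize(2 * x + 1, x), 0.0)

    def test_orthogonal_regressor_leaves_centered_outcome(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(2001)
        x = np.repeat([0.0, 1.0], [1000, 1001])  # essentially independent of y
        r = residualize(y, x)
        assert np.corrcoef(r, y - y.mean())[0, 1] > 0.99

    def test_distance_mediated_switch_cost_vanishes_after_residualization(self):
        rng = np.random.default_rng(1)
        n = 4000
        cond = rng.integers(0, 2, n)              # 1 = switch
        dist = rng.choice(np.arange(11.25, 80, 11.25), n)
        dist[cond == 1] += 15                     # switches have larger distances
        y = -0.02 * dist + rng.standard_normal(n) * 0.1  # cost driven by distance only
        raw_cost = y[cond == 1].mean() - y[cond == 0].mean()
        r = residualize(y, dist)
        res_cost = r[cond == 1].mean() - r[cond == 0].mean()
        assert abs(raw_cost) > 0.25
        assert abs(res_cost) < 0.02

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            residualize(np.arange(4.0), np.ones(4))
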