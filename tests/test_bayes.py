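"""Tests for DOB computation, HPD intervals, hierarchical fits, contrasts
and the power simulation."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from gastrokin import (
    DataError,
    HierarchicalModelSpec,
    analytic_z_power,
    compute_dob,
    contrasts,
    fit_hierarchical,
    hpd_interval,
    power_simulation,
    simulate_timeseries,
)
from gastrokin.synthetic import GroundTruth

from conftest import single_arm_design


def _quiet_fit(records, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hierarchical(records, spec)


class TestComputeDob:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["subject_id", "arm", "measure", "time_min", "value", "is_baseline"],
        )

    def test_subtracts_baseline_mean(self):
        df = self._frame(
            [
                ("S01", "PS-LE1", "cck", -15.0, 5.0, True),
                ("S01", "PS-LE1", "cck", -5.0, 5.2, True),
                ("S01", "PS-LE1", "cck", 10.0, 6.1, False),
            ]
        )
        out, n_skipped = compute_dob(df)
        assert n_skipped == 0
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_series_equal_to_baseline_gives_zero(self):
        df = self._frame(
            [("S01", "A", "m", -5.0, 3.0, True)]
            + [("S01", "A", "m", t, 3.0, False) for t in (10.0, 20.0, 30.0)]
        )
        out, _ = compute_dob(df)
        assert np.allclose(out["value"], 0.0)

    def test_missing_baseline_skips_series_with_warning(self):
        df = self._frame(
            [
                ("S01", "A", "m", 10.0, 1.0, False),
                ("S02", "A", "m", -5.0, 0.5, True),
                ("S02", "A", "m", 10.0, 1.5, False),
            ]
        )
        with pytest.warns(UserWarning, match="without baseline"):
            out, n_skipped = compute_dob(df)
        assert n_skipped == 1
        assert set(out["subject_id"]) == {"S02"}

    def test_roundtrip_against_generator_raw_mode(self, truth):
        sub = truth.subset(["cck"])
        d = single_arm_design(6, seed=41)
        raw, _ = simulate_timeseries(d, sub, raw_mode=True)
        dob, n_skipped = compute_dob(raw)
        assert n_skipped == 0
        # recompute the identity by hand for one series
        sid = dob["subject_id"].iloc[0]
        r = raw[raw["subject_id"] == sid]
        expected = (
            r[~r["is_baseline"]]["value"].to_numpy()
            - r[r["is_baseline"]]["value"].mean()
        )
        got = dob[dob["subject_id"] == sid]["value"].to_numpy()
        np.testing.assert_allclose(got, expected)


class TestHpd:
    def test_standard_normal_matches_equal_tail(self):
        draws = np.random.default_rng(0).standard_normal(10_000)
        lo, hi = hpd_interval(draws)
        assert lo == pytest.approx(-1.96, abs=0.08)
        assert hi == pytest.approx(1.96, abs=0.08)

    def test_constant_vector(self):
        lo, hi = hpd_interval(np.full(500, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_skewed_sample_left_anchored_and_shorter(self):
        draws = np.random.default_rng(1).exponential(1.0, 10_000)
        lo, hi = hpd_interval(draws, 0.95)
        et = (np.quantile(draws, 0.025), np.quantile(draws, 0.975))
        assert hi - lo <= et[1] - et[0]
        assert lo <= np.quantile(draws, 0.01)

    def test_agrees_with_arviz(self):
        import arviz as az

        draws = np.random.default_rng(2).gamma(3.0, 2.0, 5_000)
        lo, hi = hpd_interval(draws)
        ref = az.hdi(draws, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.1)
        assert hi == pytest.approx(ref[1], abs=0.1)

    def test_mass_shift_invariance(self):
        draws = np.random.default_rng(3).standard_normal(2_000)
        lo, hi = hpd_interval(draws)
        lo2, hi2 = hpd_interval(draws + 10.0)
        assert lo2 == pytest.approx(lo + 10.0)
        assert hi2 == pytest.approx(hi + 10.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(50))
        with pytest.raises(ValueError):
            hpd_interval(np.arange(200), mass=1.5)


class TestContrasts:
    def _draws(self, **arms):
        return {
            name: {"v0": np.asarray(vals, dtype=float).reshape(2, -1)}
            for name, vals in arms.items()
        }

    def test_identical_arms_centred_on_zero(self):
        x = np.random.default_rng(0).normal(size=400)
        res = contrasts(self._draws(A=x, B=x), "v0", pairs=[("A", "B")])[0]
        assert res.median == 0.0
        assert not res.excludes_zero

    def test_constant_shift(self):
        x = np.random.default_rng(0).normal(size=400)
        res = contrasts(self._draws(A=x, B=x + 10), "v0", pairs=[("A", "B")])[0]
        assert res.median == pytest.approx(10.0)
        assert (res.hpd_low, res.hpd_high) == (pytest.approx(10.0), pytest.approx(10.0))
        assert res.excludes_zero

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        d = self._draws(A=rng.normal(size=400), B=rng.normal(1.0, 1.0, 400))
        ab = contrasts(d, "v0", pairs=[("A", "B")])[0]
        ba = contrasts(d, "v0", pairs=[("B", "A")])[0]
        assert ab.median == pytest.approx(-ba.median)
        assert ab.hpd_low == pytest.approx(-ba.hpd_high)
        assert ab.hpd_high == pytest.approx(-ba.hpd_low)

    def test_all_pairs_emitted(self):
        rng = np.random.default_rng(5)
        d = self._draws(
            **{n: rng.normal(size=400) for n in ("A", "B", "C", "D")}
        )
        res = contrasts(d, "v0")
        assert len(res) == 6

    def test_missing_arm_named_in_error(self):
        d = self._draws(A=np.zeros(400))
        with pytest.raises(DataError, match="'B'"):
            contrasts(d, "v0", pairs=[("A", "B")])


class TestHierarchicalFit:
    def test_noise_free_recovery_single_measure(self, noise_free_truth):
        sub = GroundTruth({"fat": noise_free_truth.measures["fat"]})
        d = single_arm_design(5, seed=51)
        rec, _ = simulate_timeseries(d, sub)
        spec = HierarchicalModelSpec("fat", "linexp", warmup=400, draws=500, seed=1)
        fit = _quiet_fit(rec, spec)
        pop = sub.measures["fat"].params["PS-LE1"]
        med = {s.parameter: s.median for s in fit.summaries}
        assert med["v0"] == pytest.approx(pop.v0, rel=0.01)
        assert med["k"] == pytest.approx(pop.k, rel=0.01)
        assert med["t_const"] == pytest.approx(pop.t_const, rel=0.01)

    def test_posterior_median_matches_ols_intercept_in_linear_regime(self):
        # with T >> t the LinExp curve is affine in t, so the fitted V0 must
        # agree with the straight-line OLS intercept
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 2.0, 9)
        rows = []
        for s in range(4):
            y = 35.0 * (1 - t / 500.0) + rng.normal(0, 0.05, t.size)
            rows += [
                (f"S{s:02d}", "PS-LE1", "fat", ti, yi, False)
                for ti, yi in zip(t, y)
            ]
        rec = pd.DataFrame(
            rows,
            columns=["subject_id", "arm", "measure", "time_min", "value", "is_baseline"],
        )
        pooled = rec.groupby("time_min")["value"].mean().reset_index()
        slope, intercept = np.polyfit(pooled["time_min"], pooled["value"], 1)
        spec = HierarchicalModelSpec(
            "fat", "linexp", warmup=400, draws=500, seed=2, t_bounds=(1.0, 5000.0)
        )
        fit = _quiet_fit(rec, spec)
        v0 = [s for s in fit.summaries if s.parameter == "v0"][0]
        assert v0.median == pytest.approx(intercept, rel=0.01)

    def test_derived_quantities_are_drawwise(self, truth):
        sub = truth.subset(["cck"])
        d = single_arm_design(5, seed=61)
        rec, _ = simulate_timeseries(d, sub)
        spec = HierarchicalModelSpec("cck", "powerexp", warmup=400, draws=500, seed=3)
        fit = _quiet_fit(rec, spec)
        k = fit.arm_draws("PS-LE1", "k")
        beta = fit.arm_draws("PS-LE1", "beta")
        t_max = fit.arm_draws("PS-LE1", "t_max")
        np.testing.assert_allclose(t_max, np.log(beta) / k, rtol=1e-12)
        med = [s for s in fit.summaries if s.parameter == "t_max"][0].median
        assert med == pytest.approx(float(np.median(np.log(beta) / k)), rel=1e-12)

    def test_seed_reproducibility(self, truth):
        sub = truth.subset(["fat"])
        d = single_arm_design(4, seed=71)
        rec, _ = simulate_timeseries(d, sub)
        spec = HierarchicalModelSpec("fat", "linexp", warmup=300, draws=500, seed=9)
        f1 = _quiet_fit(rec, spec)
        f2 = _quiet_fit(rec, spec)
        for s1, s2 in zip(f1.summaries, f2.summaries):
            assert s1 == s2

    def test_summary_invariants(self, truth):
        sub = truth.subset(["fat"])
        d = single_arm_design(4, seed=73)
        rec, _ = simulate_timeseries(d, sub)
        spec = HierarchicalModelSpec("fat", "linexp", warmup=300, draws=500, seed=10)
        fit = _quiet_fit(rec, spec)
        for s in fit.summaries:
            assert s.hpd_low <= s.median <= s.hpd_high
            assert s.ess > 0

    def test_too_few_subjects_rejected(self):
        rec = pd.DataFrame(
            {
                "subject_id": ["S01"] * 5,
                "arm": "PS-LE1",
                "measure": "fat",
                "time_min": [0.0, 20.0, 40.0, 60.0, 90.0],
                "value": [35.0, 34.0, 32.0, 30.0, 27.0],
                "is_baseline": False,
            }
        )
        spec = HierarchicalModelSpec("fat", "linexp")
        with pytest.raises(DataError):
            fit_hierarchical(rec, spec)

    def test_constant_series_rejected(self):
        rows = []
        for s in ("S01", "S02"):
            rows += [(s, "A", "fat", t, 10.0, False) for t in (0.0, 20.0, 40.0, 60.0)]
        rec = pd.DataFrame(
            rows,
            columns=["subject_id", "arm", "measure", "time_min", "value", "is_baseline"],
        )
        with pytest.raises(DataError, match="constant"):
            fit_hierarchical(rec, HierarchicalModelSpec("fat", "linexp"))

    def test_empty_measure_rejected(self):
        rec = pd.DataFrame(
            columns=["subject_id", "arm", "measure", "time_min", "value", "is_baseline"]
        )
        with pytest.raises(DataError):
            fit_hierarchical(rec, HierarchicalModelSpec("fat", "linexp"))

    def test_identical_arms_rarely_flagged(self, truth):
        # duplicate-arm null check through the full MCMC contrast machinery
        import dataclasses as dc

        mt = truth.measures["fat"]
        flags = 0
        reps = 8
        for i in range(reps):
            frames = []
            for j, arm in enumerate(("A", "B")):
                pair = GroundTruth(
                    {"fat": dc.replace(mt, params={arm: mt.params["PS-LE1"]})}
                )
                d = single_arm_design(5, seed=500 + 10 * i + j, arm=arm)
                rec, _ = simulate_timeseries(d, pair)
                frames.append(rec)
            rec = pd.concat(frames, ignore_index=True)
            spec = HierarchicalModelSpec(
                "fat", "linexp", warmup=400, draws=500, seed=600 + i
            )
            fit = _quiet_fit(rec, spec)
            res = contrasts(fit, "v0", pairs=[("A", "B")])[0]
            flags += int(res.excludes_zero)
        assert flags <= 2


class TestPowerSimulation:
    def test_null_detection_near_alpha(self):
        res = power_simulation(effect=0.0, alpha=0.05, reps=400, seed=1)
        se = math.sqrt(0.05 * 0.95 / 400)
        assert abs(res.power - 0.05) <= 3 * se

    def test_large_effect_detected_always(self):
        res = power_simulation(effect=10.0, alpha=0.01, reps=200, seed=2)
        assert res.power == 1.0

    def test_matches_analytic_z_power(self):
        # configuration chosen so the closed-form z-power is ~0.85
        target = analytic_z_power(1.0, 15, 0.01, 0.76)
        res = power_simulation(
            effect=1.0, n_per_arm=15, alpha=0.01, reps=800, rate_sd=0.76, seed=3
        )
        se = math.sqrt(target * (1 - target) / 800)
        assert abs(res.power - target) <= 3 * se

    def test_too_few_reps_rejected(self):
        with pytest.raises(Exception):
            power_simulation(effect=0.0, reps=10)
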