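"""Invasion-factor scoring: formula, calibration, onset, ranking, wounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonotrace import invasion as inv
from clonotrace.invasion import (DEFAULT_BETA0, DEFAULT_BETA1,
                                 InvasionCoefficients, InvasionTimecourse,
                                 WoundTimecourse)


def make_tc(times, areas, clone="x"):
    return InvasionTimecourse(clone_id=clone, times=np.asarray(times, float),
                              areas=np.asarray(areas, float))


class TestOnsetDetection:
    def test_flat_series_never_starts(self):
        tc = make_tc(np.arange(0, 49), np.full(49, 100.0))
        assert inv.detect_invasion_start(tc) is None

    def test_step_onset_at_12h(self):
        times = np.arange(0, 49)
        areas = np.where(times < 12, 100.0, 150.0)
        assert inv.detect_invasion_start(tc := make_tc(times, areas)) == 12.0

    def test_immediate_growth_returns_first_post_baseline_frame(self):
        tc = make_tc([0, 1, 2, 3], [100, 120, 140, 160])
        assert inv.detect_invasion_start(tc) == 1.0

    def test_transient_blip_is_ignored(self):
        # single above-threshold frame does not satisfy consecutive = 2
        tc = make_tc([0, 1, 2, 3, 4], [100, 120, 100, 100, 100])
        assert inv.detect_invasion_start(tc) is None

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            inv.detect_invasion_start(make_tc([0, 1], [0, 10]))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 1e6), st.integers(2, 40))
    def test_invariant_under_uniform_rescaling(self, scale, t0):
        times = np.arange(0, 49)
        areas = np.where(times < t0, 50.0, 80.0)
        a = inv.detect_invasion_start(make_tc(times, areas))
        b = inv.detect_invasion_start(make_tc(times, areas * scale))
        assert a == b == float(t0)


class TestRelativeArea:
    def test_single_clone_self_normalizes(self):
        tc = make_tc([0, 24, 48], [100, 300, 900])
        assert inv.relative_invasion_area([tc]) == {"x": pytest.approx(1.0)}

    def test_two_clone_mean_normalization(self):
        a = make_tc([0, 48], [100, 200], clone="a")  # fold 2
        b = make_tc([0, 48], [100, 400], clone="b")  # fold 4
        rel = inv.relative_invasion_area([a, b])
        assert rel["a"] == pytest.approx(2 / 3)
        assert rel["b"] == pytest.approx(4 / 3)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(3)
        cohort, folds = [], []
        for i in range(6):
            f = rng.uniform(1, 5)
            cohort.append(make_tc([0, 48], [100, 100 * f], clone=f"c{i}"))
            folds.append(f)
        rel = inv.relative_invasion_area(cohort)
        for i, f in enumerate(folds):
            assert rel[f"c{i}"] == pytest.approx(f / np.mean(folds))
        assert np.mean(list(rel.values())) == pytest.approx(1.0)

    def test_missing_coverage_rejected(self):
        tc = make_tc([0, 24], [100, 200])
        with pytest.raises(ValueError, match="coverage"):
            inv.relative_invasion_area([tc], t_eval=48.0)


class TestCalibration:
    def test_recovers_printed_constants_from_noiseless_pairs(self):
        t = np.linspace(2, 40, 12)
        a = np.exp(DEFAULT_BETA0 + DEFAULT_BETA1 * t)
        coef = inv.calibrate_invasion_model(list(zip(t, a)))
        assert coef.beta0 == pytest.approx(DEFAULT_BETA0, abs=1e-9)
        assert coef.beta1 == pytest.approx(DEFAULT_BETA1, abs=1e-9)
        assert coef.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_log_area(self):
        coef = inv.calibrate_invasion_model([(1, 2.0), (2, 2.0), (3, 2.0)])
        assert coef.beta1 == 0.0
        assert coef.r_squared == 0.0

    def test_noisy_recovery_within_ci(self):
        # truth inside the marginal 95% CI in >= 93/100 seeded replicates
        n_rep, n_clones, sigma = 100, 20, 0.5
        cover0 = cover1 = 0
        from scipy import stats as sps
        tq = sps.t.ppf(0.975, n_clones - 2)
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            t = rng.uniform(2, 40, n_clones)
            lna = DEFAULT_BETA0 + DEFAULT_BETA1 * t + rng.normal(0, sigma, n_clones)
            coef = inv.calibrate_invasion_model(list(zip(t, np.exp(lna))))
            # standard OLS standard errors
            sxx = np.sum((t - t.mean()) ** 2)
            resid = lna - coef.beta0 - coef.beta1 * t
            s2 = resid @ resid / (n_clones - 2)
            se1 = np.sqrt(s2 / sxx)
            se0 = np.sqrt(s2 * (1 / n_clones + t.mean() ** 2 / sxx))
            cover0 += abs(coef.beta0 - DEFAULT_BETA0) <= tq * se0
            cover1 += abs(coef.beta1 - DEFAULT_BETA1) <= tq * se1
        assert cover0 >= 93
        assert cover1 >= 93

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            inv.calibrate_invasion_model([(1, 1.0), (2, 0.0), (3, 2.0)])


class TestInvasionFactor:
    def test_closed_form_at_t_zero(self):
        expected = (1 + np.exp(86539 / 44760)) / 2
        assert inv.invasion_factor(1.0, 0.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.956, abs=5e-4)

    def test_unity_at_exponent_root(self):
        t_root = -DEFAULT_BETA0 / DEFAULT_BETA1  # ~8.654 h
        assert t_root == pytest.approx(8.654, abs=1e-3)
        assert inv.invasion_factor(1.0, t_root) == pytest.approx(1.0, rel=1e-12)

    def test_limit_zero(self):
        assert inv.invasion_factor(0.0, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_in_t_increasing_in_A(self):
        ts = np.linspace(0, 48, 97)
        ifs = [inv.invasion_factor(1.0, t) for t in ts]
        assert np.all(np.diff(ifs) < 0)
        As = np.linspace(0, 5, 51)
        ifs = [inv.invasion_factor(a, 12.0) for a in As]
        assert np.all(np.diff(ifs) > 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            inv.invasion_factor(-0.1, 1.0)
        with pytest.raises(ValueError):
            inv.invasion_factor(1.0, -1.0)

    def test_roundtrip_with_calibration(self):
        # on the fitted curve A = exp(b0 + b1 t), IF = A exactly
        t = np.linspace(2, 40, 10)
        a = np.exp(DEFAULT_BETA0 + DEFAULT_BETA1 * t)
        coef = inv.calibrate_invasion_model(list(zip(t, a)))
        for ti, ai in zip(t, a):
            assert inv.invasion_factor(ai, ti, coef) == pytest.approx(ai, rel=1e-9)


class TestRanking:
    def test_four_clone_arithmetic(self):
        # choose (A, t) so IFs are 1, 2, 3, 4: A = 2 IF - exp term
        coef = InvasionCoefficients()
        t = 12.0
        e = np.exp(coef.beta0 + coef.beta1 * t)
        entries = [(f"c{k}", 2 * k - e, t) for k in (1, 2, 3, 4)]
        scores = inv.rank_clones(entries)
        assert [s.rank for s in scores] == [4, 3, 2, 1]
        np.testing.assert_allclose(
            [s.relative_invasiveness for s in scores], [0.4, 0.8, 1.2, 1.6])

    def test_identical_clones_all_mid(self):
        scores = inv.rank_clones([(f"c{i}", 1.0, 12.0) for i in range(6)])
        assert all(s.relative_invasiveness == pytest.approx(1.0) for s in scores)
        assert all(s.invasiveness_class == "mid" for s in scores)

    def test_twenty_clones_quartiles_give_five_high_five_low(self):
        rng = np.random.default_rng(5)
        entries = [(f"c{i:02d}", float(a), float(t))
                   for i, (a, t) in enumerate(
                       zip(rng.uniform(0.2, 3.0, 20), rng.uniform(2, 40, 20)))]
        scores = inv.rank_clones(entries)
        classes = [s.invasiveness_class for s in scores]
        assert classes.count("high") == 5
        assert classes.count("low") == 5
        # class membership matches the IF ordering
        by_rank = sorted(scores, key=lambda s: s.rank)
        assert all(s.invasiveness_class == "high" for s in by_rank[:5])
        assert all(s.invasiveness_class == "low" for s in by_rank[-5:])

    def test_relative_invasiveness_averages_to_one(self):
        rng = np.random.default_rng(11)
        entries = [(f"c{i}", float(rng.uniform(0.1, 4)), float(rng.uniform(0, 40)))
                   for i in range(9)]
        scores = inv.rank_clones(entries)
        assert np.mean([s.relative_invasiveness for s in scores]) == pytest.approx(1.0)

    def test_small_cohort_warns_and_skips_classing(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            scores = inv.rank_clones([("a", 1.0, 5.0), ("b", 2.0, 8.0)])
        assert all(s.invasiveness_class is None for s in scores)
        assert sorted(s.rank for s in scores) == [1, 2]

    def test_outer_vs_mid_comparison(self):
        entries = [(f"c{i}", float(a), 12.0)
                   for i, a in enumerate([0.1, 0.9, 1.0, 1.1, 1.0, 4.0])]
        scores = inv.rank_clones(entries)
        reps = {s.clone_id: [s.invasion_factor + d for d in (-0.05, 0.0, 0.05)]
                for s in scores}
        res = inv.outer_vs_mid_anova(scores, reps, seed=0)
        outer = {s.clone_id for s in scores
                 if s.invasiveness_class in ("high", "low")}
        assert set(res) == outer
        assert all(r.f_statistic >= 0 for r in res.values())


class TestWoundClosure:
    def test_exact_linear_closure(self):
        times = np.arange(0, 25, 4.0)
        tc = WoundTimecourse("w", times, np.minimum(100, 10 * times))
        slope, fit = inv.wound_closure_rate(tc)
        assert slope == pytest.approx(10.0)

    def test_constant_density_zero_slope(self):
        tc = WoundTimecourse("w", np.arange(0, 25, 4.0), np.full(7, 20.0))
        slope, _ = inv.wound_closure_rate(tc)
        assert slope == 0.0

    def test_truncation_matches_least_squares_oracle(self):
        times = np.arange(0, 25, 4.0)
        dens = np.clip(100 / (1 + np.exp(-(times - 8) / 3)), 0, 100)
        tc = WoundTimecourse("w", times, dens)
        slope, fit = inv.wound_closure_rate(tc)
        reached = np.flatnonzero(dens >= 100)
        end = reached[0] if reached.size else len(times)
        coef = np.polyfit(times[:end], dens[:end], 1)
        assert slope == pytest.approx(coef[0])

    def test_instant_closure_rejected(self):
        tc = WoundTimecourse("w", [0.0, 4.0, 8.0], [50.0, 100.0, 100.0])
        with pytest.raises(ValueError, match="closed by frame"):
            inv.wound_closure_rate(tc)


class TestSpheroidVolume:
    @pytest.mark.parametrize("a0, a1, expected", [
        (1.0, 2.0, 2 ** 1.5),
        (3.0, 3.0, 1.0),
        (1.0, 4.0, 8.0),
    ])
    def test_sphere_geometry(self, a0, a1, expected):
        assert inv.spheroid_volume_increase(a0, a1) == pytest.approx(expected)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            inv.spheroid_volume_increase(0.0, 1.0)


class TestIO:
    def test_invasion_csv_roundtrip(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({"clone_id": ["a", "a", "b", "b"],
                           "time_h": [0, 48, 0, 48],
                           "area": [100, 300, 100, 150]})
        p = tmp_path / "tc.csv"
        df.to_csv(p, index=False)
        cohort = inv.read_invasion_csv(p)
        assert [tc.clone_id for tc in cohort] == ["a", "b"]
        rel = inv.relative_invasion_area(cohort)
        assert rel["a"] == pytest.approx(3 / 2.25)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("clone_id,time_h\na,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            inv.read_invasion_csv(p)
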