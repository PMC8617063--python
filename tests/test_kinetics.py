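"""Enzyme-kinetics unit tests: velocities, Morrison fits, Ki chains."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thrombokit.kinetics import (
    CompetitiveKiModel,
    InhibitionSeries,
    LogisticIC50Model,
    MorrisonModel,
    ProgressCurve,
    estimate_velocity,
    fractional_velocities,
    ki_fold_ratio,
    morrison_velocity,
    noncompetitive_ki,
    percent_inhibition,
    selectivity_fold,
)

GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _curve(slope_au_min, n=121, dt=5.0, a0=0.3, it=0.0, noise=None, seed=0):
    t = np.arange(n) * dt
    a = a0 + slope_au_min * t / 60.0
    if noise:
        a = a + np.random.default_rng(seed).normal(0, noise, n)
    return ProgressCurve(t, a, Et_nM=0.8, It_nM=it, S_uM=100.0)


class TestEstimateVelocity:
    def test_exact_line(self):
        est = estimate_velocity(_curve(0.010))
        assert est.v_au_per_min == pytest.approx(0.010, rel=1e-12)
        assert est.r_squared == 1.0

    def test_constant_trace_zero_velocity(self):
        est = estimate_velocity(_curve(0.0))
        assert est.v_au_per_min == pytest.approx(0.0, abs=1e-15)

    def test_matches_normal_equations_oracle(self):
        c = _curve(0.02, noise=0.001, seed=42)
        est = estimate_velocity(c)
        # closed-form OLS slope in minutes
        tm = c.time_s / 60.0
        a = c.absorbance_au
        slope = (np.sum((tm - tm.mean()) * (a - a.mean()))
                 / np.sum((tm - tm.mean()) ** 2))
        assert est.v_au_per_min == pytest.approx(slope, abs=1e-12)

    def test_window_selects_subset(self):
        c = _curve(0.02)
        est = estimate_velocity(c, window_s=(100.0, 400.0))
        assert est.v_au_per_min == pytest.approx(0.02, rel=1e-12)
        assert est.window_s == (100.0, 400.0)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            estimate_velocity(_curve(0.02), window_s=(0.0, 1e6))

    def test_too_few_points_rejected(self):
        c = ProgressCurve(np.arange(4.0), np.zeros(4) + 0.1, Et_nM=0.8)
        with pytest.raises(ValueError, match="5 samples"):
            estimate_velocity(c)


class TestFractionalVelocities:
    def test_reference_and_ratios(self):
        curves = [_curve(0.010, it=0.0), _curve(0.005, it=0.8),
                  _curve(0.0, it=5.0), _curve(0.012, it=0.1)]
        series = fractional_velocities(curves)
        fv = dict(zip(series.It_nM, series.fractional_velocity))
        assert fv[0.0] == 1.0
        assert fv[0.8] == pytest.approx(0.5, rel=1e-9)
        assert fv[5.0] == pytest.approx(0.0, abs=1e-9)
        # activation (> 1) is permitted, as for thrombin-activating peptides
        assert fv[0.1] == pytest.approx(1.2, rel=1e-9)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            fractional_velocities([_curve(0.005, it=0.8)])


class TestMorrisonVelocity:
    def test_no_inhibitor_limit(self):
        assert morrison_velocity(0.05, 0.0, 0.8, vo=0.7) == pytest.approx(0.7)

    def test_stoichiometric_titration_limit(self):
        # at Ki' = 0 the inhibitor titrates the enzyme exactly
        assert morrison_velocity(0.0, 0.8, 0.8, vo=1.0) == pytest.approx(0.0, abs=1e-12)
        assert morrison_velocity(0.0, 0.4, 0.8, vo=1.0) == pytest.approx(0.5)

    def test_golden_ratio_point(self):
        # Ki' = It = Et gives vs/vo = (sqrt(5)-1)/2
        assert morrison_velocity(1.0, 1.0, 1.0, vo=1.0) == pytest.approx(GOLDEN, rel=1e-12)

    def test_zero_enzyme_rejected(self):
        with pytest.raises(ValueError):
            morrison_velocity(0.05, 0.1, 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(ki=st.floats(1e-4, 1e3), et=st.floats(1e-3, 10.0))
    def test_monotone_in_inhibitor_and_ki(self, ki, et):
        it = np.linspace(0.0, 5.0 * et, 30)
        vs = morrison_velocity(ki, it, et, vo=1.0)
        assert np.all(np.diff(vs) <= 1e-12)
        assert np.all(vs >= -1e-12) and np.all(vs <= 1.0 + 1e-12)
        # larger Ki' (weaker inhibitor) never lowers the velocity
        vs2 = morrison_velocity(ki * 3.0, it, et, vo=1.0)
        assert np.all(vs2 - vs >= -1e-10)


def _golden_section_ki(series, lo=1e-2, hi=1e6):
    """Independent brute-force oracle: log grid + golden-section refine
    of the Morrison RSS in Ki' (pM), vo fixed at 1."""
    def rss(ki_pM):
        fv = morrison_velocity(ki_pM / 1e3, series.It_nM, series.Et_nM, 1.0)
        return float(np.sum((fv - series.fractional_velocity) ** 2))

    grid = np.logspace(np.log10(lo), np.log10(hi), 400)
    i = int(np.argmin([rss(k) for k in grid]))
    a = np.log(grid[max(i - 1, 0)])
    b = np.log(grid[min(i + 1, grid.size - 1)])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    while abs(b - a) > 1e-12:
        if rss(np.exp(c)) < rss(np.exp(d)):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    return float(np.exp((a + b) / 2.0))


class TestMorrisonFit:
    def test_noiseless_recovery(self, tight_binding_series):
        series, ki_true_pM = tight_binding_series
        res = MorrisonModel(series).fit()
        assert res.ki_prime_pM == pytest.approx(ki_true_pM, rel=1e-6)
        assert res.tight_binding_regime  # pM-scale Ki' << 0.8 nM enzyme

    def test_matches_grid_golden_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ki = 10.0 ** rng.uniform(-2, 2)  # pM-to-sub-nM truths
            et = 10.0 ** rng.uniform(-0.5, 0.5)
            it = np.concatenate([[0.0], np.linspace(0.2, 3.0, 6) * et])
            fv = morrison_velocity(ki / 1e3, it, et, 1.0)
            series = InhibitionSeries(Et_nM=et, S_uM=100.0, It_nM=it,
                                      fractional_velocity=fv)
            fitted = MorrisonModel(series).fit().ki_prime_pM
            oracle = _golden_section_ki(series)
            assert fitted == pytest.approx(oracle, rel=1e-4)

    def test_round_trip_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ki_nM = 10.0 ** rng.uniform(-4, 0)
            et = 10.0 ** rng.uniform(-1, 1)
            it = np.concatenate([[0.0], np.geomspace(0.1, 4.0, 6) * et])
            fv = morrison_velocity(ki_nM, it, et, 1.0)
            series = InhibitionSeries(Et_nM=et, S_uM=100.0, It_nM=it,
                                      fractional_velocity=fv)
            res = MorrisonModel(series).fit()
            assert res.ki_prime_pM == pytest.approx(ki_nM * 1e3, rel=1e-6)

    def test_fitted_vo_mode(self, tight_binding_series):
        series, ki_true_pM = tight_binding_series
        res = MorrisonModel(series, vo_mode="fitted").fit()
        assert res.ki_prime_pM == pytest.approx(ki_true_pM, rel=1e-5)
        assert res.vo == pytest.approx(1.0, rel=1e-6)

    def test_degenerate_input_rejected(self):
        series = InhibitionSeries(Et_nM=0.8, S_uM=100.0,
                                  It_nM=np.array([0.0, 0.4, 0.8, 1.2]),
                                  fractional_velocity=np.ones(4))
        with pytest.raises(ValueError, match="degenerate"):
            MorrisonModel(series)

    def test_summary_mentions_parameters(self, tight_binding_series):
        series, _ = tight_binding_series
        text = MorrisonModel(series).fit().summary()
        assert "Ki'" in text and "tight-binding" in text


class TestCompetitiveKi:
    def test_exact_line(self):
        # Ki = 4 pM, Km = 100 uM: Ki'(S) = 4 * (1 + S/100)
        res = CompetitiveKiModel([100, 200, 400], [8.0, 12.0, 20.0]).fit()
        assert res.ki_pM == pytest.approx(4.0, rel=1e-9)
        assert res.km_uM == pytest.approx(100.0, rel=1e-9)
        assert res.mode_call == "competitive_consistent"

    def test_flat_series_flagged_noncompetitive_pattern(self):
        res = CompetitiveKiModel([100, 200, 400], [5.0, 5.0, 5.0]).fit()
        assert res.mode_call == "nonlinear"
        assert np.isnan(res.km_uM)

    def test_weighted_regression_prefers_precise_points(self):
        S = np.array([100.0, 200.0, 400.0, 800.0])
        kip = 4.0 * (1.0 + S / 100.0)
        kip_off = kip.copy()
        kip_off[-1] *= 1.3  # corrupt the least precise point
        se = np.array([0.1, 0.1, 0.1, 50.0])
        res_w = CompetitiveKiModel(S, kip_off, se).fit()
        res_u = CompetitiveKiModel(S, kip_off).fit()
        assert abs(res_w.ki_pM - 4.0) < abs(res_u.ki_pM - 4.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            CompetitiveKiModel([100, 100, 200], [8, 8, 12])


class TestLogisticIC50:
    def _data(self, ic50=1.66, h=1.0, a1=0.0, a2=100.0):
        conc = np.geomspace(0.01, 300.0, 9)
        x = np.log10(conc)
        y = a2 + (a1 - a2) / (1.0 + 10.0 ** (h * (x - np.log10(ic50))))
        return conc, y

    def test_noiseless_recovery(self):
        conc, y = self._data()
        res = LogisticIC50Model(conc, y).fit()
        assert res.ic50 == pytest.approx(1.66, rel=1e-3)
        assert res.H == pytest.approx(1.0, rel=1e-6)

    def test_inflection_identity(self):
        conc, y = self._data(ic50=2.5, h=1.7, a1=5.0, a2=95.0)
        res = LogisticIC50Model(conc, y).fit()
        assert res.predict([res.ic50])[0] == pytest.approx((res.A1 + res.A2) / 2.0)

    def test_matches_profiled_grid_oracle(self):
        conc, y = self._data(ic50=3.3, h=1.4)
        x = np.log10(conc)

        def profiled_rss(x0, h):
            w = 1.0 / (1.0 + 10.0 ** (h * (x - x0)))  # weight on A1
            A = np.column_stack([w, 1.0 - w])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(np.sum((A @ coef - y) ** 2))

        grid_x0 = np.linspace(-1.0, 2.0, 301)
        grid_h = np.linspace(0.3, 3.0, 271)
        rss = np.array([[profiled_rss(a, b) for b in grid_h] for a in grid_x0])
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        res = LogisticIC50Model(conc, y).fit()
        assert res.x0 == pytest.approx(grid_x0[i], abs=0.02)
        assert res.H == pytest.approx(grid_h[j], abs=0.02)

    def test_constrained_asymptotes(self):
        conc, y = self._data()
        res = LogisticIC50Model(conc, y, constrained=True).fit()
        assert (res.A1, res.A2) == (0.0, 100.0)
        assert res.ic50 == pytest.approx(1.66, rel=1e-3)

    def test_constant_responses_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            LogisticIC50Model([1, 10, 100, 1000], [50, 50, 50, 50])


class TestKiChainsAndPanels:
    def test_noncompetitive_ki_is_ic50_passthrough(self):
        conc = np.geomspace(0.01, 300.0, 8)
        x = np.log10(conc)
        y = 100.0 - 100.0 / (1.0 + 10.0 ** (x - np.log10(1.66)))
        fit = LogisticIC50Model(conc, y).fit()
        ki = noncompetitive_ki(fit)
        assert ki.ki == pytest.approx(fit.ic50)
        # annotation survives serialization
        d = ki.to_dict()
        assert d["mode"].startswith("non-competitive") and d["unit"] == "nM"

    def test_percent_inhibition(self):
        assert percent_inhibition(1.0, 1.0) == 0.0
        assert percent_inhibition(0.0, 1.0) == 100.0
        assert percent_inhibition(1.2, 1.0) == pytest.approx(-20.0)
        with pytest.raises(ValueError):
            percent_inhibition(0.5, 0.0)

    def test_selectivity_bound_from_panel(self):
        rows = [{"protease_id": "thrombin", "inhibitor_conc_nM": 0.1,
                 "pct_inhibition": 27.0}]
        for prot in ["trypsin", "fXa", "plasmin", "kallikrein"]:
            rows.append({"protease_id": prot, "inhibitor_conc_nM": 1e5,
                         "pct_inhibition": 12.0})
        res = selectivity_fold(pd.DataFrame(rows), "thrombin", 20.0)
        assert res.fold >= 1e6
        assert res.selective

    def test_selectivity_identical_concentrations(self):
        df = pd.DataFrame([
            {"protease_id": "thrombin", "inhibitor_conc_nM": 1.0, "pct_inhibition": 50.0},
            {"protease_id": "trypsin", "inhibitor_conc_nM": 1.0, "pct_inhibition": 5.0},
        ])
        assert selectivity_fold(df, "thrombin").fold == pytest.approx(1.0)

    def test_selectivity_nonselective_flagged(self):
        df = pd.DataFrame([
            {"protease_id": "thrombin", "inhibitor_conc_nM": 10.0, "pct_inhibition": 60.0},
            {"protease_id": "trypsin", "inhibitor_conc_nM": 1.0, "pct_inhibition": 5.0},
        ])
        res = selectivity_fold(df, "thrombin")
        assert res.fold < 1.0 and not res.selective

    @pytest.mark.parametrize("ki_a,ki_b,expected", [
        (1780.0, 4.0, 445.0),
        (1660.0, 4.0, 415.0),
        (624.0, 6.5, 96.0),
        (7.0, 7.0, 1.0),
    ])
    def test_fold_ratio(self, ki_a, ki_b, expected):
        assert ki_fold_ratio(ki_a, ki_b, "nearest_integer") == expected

    def test_fold_ratio_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ki_fold_ratio(0.0, 4.0)
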