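"""Empirical correlation fits, guideline tables and Taylor–Aris comparison."""

import numpy as np
import pandas as pd
import pytest

from itdisp import correlations as corr
from itdisp import csf_dynamics as csf
from itdisp import synthetic_data as synth
from itdisp.correlations import (
    PAPER_MODEL,
    TAYLOR_STATIONARY,
    WATSON_OSCILLATORY,
    fit_dd10,
    fit_dimensionless,
    fit_logD,
    predict_dd10,
    predict_delta_d,
    predict_logD,
    taylor_prediction,
)


class TestDD10:
    @pytest.mark.parametrize("nd,ivf,printed", [
        (0.2, 1.00, 22.48),
        (3.2, 2.00, 21.08),
        (0.5, 1.00, 22.05),
        (1.0, 2.00, 24.19),
    ])
    def test_prediction_matches_printed_cells(self, nd, ivf, printed):
        assert predict_dd10(nd, ivf) == pytest.approx(printed, abs=0.05)

    def test_monotonicity(self):
        # wider flow spreads farther; wider needles spread less
        assert predict_dd10(0.2, 2.0) > predict_dd10(0.2, 1.0)
        assert predict_dd10(3.2, 1.0) < predict_dd10(0.2, 1.0)

    def test_noiseless_fixed_point(self):
        table = synth.generate_experiment_table(noise_sd=0.0, seed=0)
        res = fit_dd10(table)
        assert res["a"] == pytest.approx(-1.4150, abs=1e-10)
        assert res["b"] == pytest.approx(2.8786, abs=1e-10)
        assert res["c"] == pytest.approx(19.8668, abs=1e-10)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_degenerates_to_intercept(self):
        table = pd.DataFrame({
            "nd_mm": [0.2, 1.0, 3.2, 0.2, 1.0, 3.2],
            "ivf_ml_min": [0.5, 0.5, 0.5, 2.0, 2.0, 2.0],
            "dd10_cm": [21.0] * 6,
        })
        res = fit_dd10(table)
        assert res["a"] == pytest.approx(0.0, abs=1e-10)
        assert res["b"] == pytest.approx(0.0, abs=1e-10)
        assert res["c"] == pytest.approx(21.0, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        table = pd.DataFrame({
            "nd_mm": [0.2] * 6,
            "ivf_ml_min": [1.0] * 6,
            "dd10_cm": np.linspace(20, 22, 6),
        })
        with pytest.raises(ValueError, match="nd_mm"):
            fit_dd10(table)

    def test_noisy_recovery_within_three_se(self):
        # noise calibrated to the published R^2 at n = 54; coefficient
        # estimates stay within 3 standard errors of truth across seeds
        a, b, c = PAPER_MODEL.dd10
        misses = 0
        for seed in range(100):
            table = synth.generate_experiment_table(seed=seed)
            res = fit_dd10(table)
            for name, truth in (("a", a), ("b", b), ("c", c)):
                lo, hi = res["ci"][name]
                se = (hi - lo) / 2 / 1.96  # approx from the 95% interval
                if abs(res[name] - truth) > 3 * se:
                    misses += 1
        assert misses <= 5


class TestCCV:
    def test_default_reading_is_nearly_frequency_flat(self):
        # the velocity line is intercept-dominated: CCV barely moves with f
        v40 = corr.predict_ccv(40.0)
        v120 = corr.predict_ccv(120.0)
        assert v40 == pytest.approx(0.3014 + 0.0012 * 40, abs=1e-12)
        assert abs(v120 - v40) < 0.1

    def test_literal_reading_available(self):
        assert corr.predict_ccv(40.0, literal=True) == pytest.approx(
            0.3014 * 40 + 0.0012, abs=1e-12)


class TestLogD:
    def test_lambda_f_hand_value(self):
        # a0 + a1*40 + a2*1600 with the published quadratic
        assert corr.lambda_f(40.0) == pytest.approx(-0.91277, abs=1e-4)

    def test_power_law_doubling(self):
        d1 = predict_logD(10.0, 60.0)
        d2 = predict_logD(20.0, 60.0)
        assert d2 / d1 == pytest.approx(2 ** 0.7419, rel=1e-12)

    def test_monotone_in_urms_and_f_below_vertex(self):
        kappa, a0, a1, a2 = PAPER_MODEL.logD
        vertex = -a1 / (2 * a2)
        assert vertex == pytest.approx(46.7, abs=0.1)
        u = np.linspace(5, 60, 20)
        d = [predict_logD(ui, 60.0) for ui in u]
        assert np.all(np.diff(d) > 0)
        f = np.linspace(1.0, vertex, 20)
        d = [predict_logD(30.0, fi) for fi in f]
        assert np.all(np.diff(d) > 0)
        f = np.linspace(vertex, 120.0, 20)
        d = [predict_logD(30.0, fi) for fi in f]
        assert np.all(np.diff(d) < 0)

    def test_nonpositive_urms_rejected(self):
        with pytest.raises(ValueError):
            predict_logD(0.0, 60.0)

    def test_noiseless_fixed_point(self):
        table = synth.generate_experiment_table(noise_sd=0.0, seed=0)
        res = fit_logD(table)
        assert res["kappa"] == pytest.approx(0.7419, abs=1e-8)
        assert res["a0"] == pytest.approx(-1.0386, abs=1e-8)
        assert res["a1"] == pytest.approx(0.0055, abs=1e-8)
        assert res["a2"] == pytest.approx(-5.8858e-5, abs=1e-10)

    def test_single_frequency_unidentifiable(self):
        design = [(0.2, 1.0, vc, 60.0) for vc in (0.25, 0.5, 0.75, 1.0)]
        table = synth.generate_experiment_table(design=design, noise_sd=0.0)
        with pytest.raises(ValueError, match="single frequency"):
            fit_logD(table)

    def test_nonpositive_rows_dropped(self):
        table = synth.generate_experiment_table(noise_sd=0.0, seed=0)
        table.loc[0, "dexp_cm2_min"] = -1.0
        res = fit_logD(table)
        assert res["kappa"] == pytest.approx(0.7419, abs=1e-8)

    def test_noisy_kappa_within_three_se(self):
        misses = 0
        for seed in range(100):
            # multiplicative noise in D keeps the log-linear model exact
            table = synth.generate_experiment_table(noise_sd=0.0, seed=seed)
            rng = np.random.default_rng(seed)
            table["dexp_cm2_min"] *= 10 ** rng.normal(0, 0.05, len(table))
            res = fit_logD(table)
            lo, hi = res["ci"]["kappa"]
            se = (hi - lo) / 2 / 1.96
            if abs(res["kappa"] - 0.7419) > 3 * se:
                misses += 1
        assert misses <= 5


class TestDimensionless:
    @staticmethod
    def _records(noise_rng=None, pe_scale=1.0, replicates=1):
        rows = []
        for vc in (0.5, 1.0):
            for f in (40, 72, 76, 120, 127):
                for _ in range(replicates):
                    state = csf.CSFState(vc=vc, f=f)
                    u = csf.urms(state, "cm/min")
                    Pe = csf.peclet(u) * pe_scale
                    alpha = csf.womersley(f)
                    dd = predict_delta_d(csf.peclet(u), alpha)
                    if noise_rng is not None:
                        dd *= 1.0 + noise_rng.normal(0, 0.1)
                    rows.append({"Pe": Pe, "alpha": alpha, "deltaD": dd})
        return pd.DataFrame(rows)

    def test_noiseless_fixed_point(self):
        res = fit_dimensionless(self._records())
        assert res["K"] == pytest.approx(0.74, abs=1e-8)
        assert res["phi0"] == pytest.approx(2.4786, abs=1e-6)
        assert res["phi1"] == pytest.approx(0.3130, abs=1e-7)
        assert res["phi2"] == pytest.approx(-0.0229, abs=1e-8)

    def test_pe_rescaling_shifts_intercept_only(self):
        res = fit_dimensionless(self._records(pe_scale=100.0))
        assert res["K"] == pytest.approx(0.74, abs=1e-8)
        assert res["phi0"] == pytest.approx(2.4786 - 0.74 * 2.0, abs=1e-6)
        assert res["phi1"] == pytest.approx(0.3130, abs=1e-7)

    def test_noisy_K_within_band(self):
        # campaign-sized record set (replicated conditions, ~N=50) with 10%
        # multiplicative scatter keeps the fitted exponent in a tight band
        ks = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = fit_dimensionless(self._records(noise_rng=rng,
                                                  replicates=5))
            ks.append(res["K"])
        assert all(0.6 <= k <= 0.9 for k in ks)


class TestTaylorAris:
    def test_pure_diffusion_limit(self):
        assert taylor_prediction(0.0, WATSON_OSCILLATORY) == 1.0
        assert taylor_prediction(0.0, TAYLOR_STATIONARY) == 1.0

    def test_watson_hand_value(self):
        assert taylor_prediction(10.0, WATSON_OSCILLATORY) == pytest.approx(
            1.0 + 0.0104 * 10 ** 1.88, rel=1e-12)

    def test_experimental_slope_shallower_than_all_theories(self):
        kappa_exp = PAPER_MODEL.logD[0]
        K_exp = PAPER_MODEL.dimless[0]
        for k in (kappa_exp, K_exp):
            assert k < WATSON_OSCILLATORY.kappa < TAYLOR_STATIONARY.kappa

    def test_theory_overshoots_experiment_by_three_decades(self):
        rep = corr.taylor_divergence_report()
        assert (rep["ratio_theory_over_experiment"] >= 1e3).all()


class TestTables:
    def test_table1_matches_print_except_suspect_cell(self):
        cmp = corr.compare_table1()
        assert cmp["max_abs_dev_excluding_suspect"] <= 0.05
        assert abs(cmp["suspect_dev"]) > 0.5  # the 20.06 outlier

    def test_table1_monotone(self):
        t1 = corr.build_table1()
        assert (t1.diff(axis=1).iloc[:, 1:] < 0).all().all()  # wider needle
        assert (t1.diff(axis=0).iloc[1:, :] > 0).all().all()  # higher flow

    def test_table2_monotone_and_anchored(self):
        t2 = corr.build_table2()
        # dispersion strictly grows with stroke volume (kappa > 0) ...
        assert (t2.diff(axis=1).iloc[:, 1:] > 0).all().all()
        # ... and with frequency while the velocity gain outweighs the
        # quadratic frequency roll-off (up to ~93 bpm for this preset)
        assert (t2.loc[:80].diff(axis=0).iloc[1:, :] > 0).all().all()
        f, vc = corr.TABLE2_ANCHOR
        assert t2.loc[f, vc] == pytest.approx(
            corr.PRINTED_TABLE2.loc[f, vc], rel=1e-9)

    def test_table2_vanishes_with_stroke_volume(self):
        A = corr.calibrate_area_from_anchor()
        d = predict_logD(csf.urms(csf.CSFState(vc=1e-6, f=60, A=A), "cm/min"),
                         60.0)
        assert d < 1e-3  # power-law limit: D -> 0 as Urms -> 0

    def test_table2_comparison_reports_deviations(self):
        cmp = corr.compare_table2()
        assert cmp["deviation"].shape == (4, 5)
        assert np.isfinite(cmp["relative_deviation"].to_numpy()).all()
        f, vc = corr.TABLE2_ANCHOR
        assert cmp["deviation"].loc[f, vc] == pytest.approx(0.0, abs=1e-9)


class TestPreset:
    def test_paper_preset_round_trips_through_json(self, paper_model):
        assert paper_model.dd10 == (-1.4150, 2.8786, 19.8668)
        assert paper_model.logD == (0.7419, -1.0386, 0.0055, -5.8858e-5)
        assert paper_model.dimless == (0.74, 2.4786, 0.3130, -0.0229)
        assert paper_model.version == 1
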