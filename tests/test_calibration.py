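"""Penalties, recalibration cost, Ca2+ sensitivity and IC50-Short fits."""

import math

import numpy as np
import pytest

from cardiotrans.calibration import (
    COST_SENTINEL,
    CalibrationTargets,
    INFERENCE_PENALTY,
    PenaltyConfig,
    RECALIBRATION_PENALTY,
    ca_sensitivity,
    ic50_short,
    range_distance,
    recalibrate,
    recalibration_cost,
    steady_state_active_stress,
    transient_penalty,
)
from cardiotrans.models import StimulusProtocol, rat_params
from cardiotrans.transients import BiomarkerSet


class TestRangeDistance:
    def test_inside_is_zero(self):
        assert range_distance(1.5, 1.0, 2.0) == 0.0
        assert range_distance(1.0, 1.0, 2.0) == 0.0  # boundary counts as inside

    def test_below_is_relative_to_lower_bound(self):
        assert range_distance(0.9, 1.0, 2.0) == pytest.approx(-0.1)

    def test_above_is_relative_to_upper_bound(self):
        assert range_distance(2.4, 1.0, 2.0) == pytest.approx(0.2)

    def test_zero_bound_rejected(self):
        with pytest.raises(ValueError):
            range_distance(0.5, 0.0, 1.0)


from helpers import TARGETS, perfect_biomarkers, synthetic_result  # noqa: E402


class TestTransientPenalty:
    def test_clean_periodic_result_has_zero_penalty(self):
        assert transient_penalty(synthetic_result(), RECALIBRATION_PENALTY) == 0.0

    def test_fluctuation_at_threshold_contributes_at_least_one(self):
        # net pre-peak SL rate of exactly +0.001 um/ms: with c2 = 1e6 the
        # squared term alone reaches 1
        base_slope = -0.09 / 50.0
        inj = 0.001 - base_slope
        res = synthetic_result(sl_kw={"fluctuation": (10.0, inj, 20.0)})
        pen = transient_penalty(res, RECALIBRATION_PENALTY)
        assert pen >= 1.0
        assert pen == pytest.approx(1.0, rel=0.15)  # dominated by the rate term

    def test_inference_coefficients_scale_floor_to_hundred(self):
        base_slope = -0.09 / 50.0
        inj = 0.001 - base_slope
        res = synthetic_result(sl_kw={"fluctuation": (10.0, inj, 20.0)})
        pen = transient_penalty(res, INFERENCE_PENALTY)
        assert pen >= 100.0

    def test_alternans_amplitude_ratio_term(self):
        res = synthetic_result(
            sl_kw={"alternans_ratio": 1.1}, ca_kw={"alternans_ratio": 1.0}
        )
        pen = transient_penalty(res, RECALIBRATION_PENALTY)
        # literal (min/max - 1)^2 form at the threshold ratio
        assert pen == pytest.approx(100.0 * (1 / 1.1 - 1) ** 2, rel=1e-2)

    def test_max_over_min_variant_reaches_unity_at_threshold(self):
        cfg = PenaltyConfig(c1=100.0, c2=1e6, amplitude_form="max_over_min")
        res = synthetic_result(
            sl_kw={"alternans_ratio": 1.1}, ca_kw={"alternans_ratio": 1.0}
        )
        assert transient_penalty(res, cfg) == pytest.approx(1.0, rel=1e-2)





class TestRecalibrationCost:
    def test_zero_iff_perfect_fit(self):
        sl, ca = perfect_biomarkers(TARGETS)
        assert recalibration_cost(sl, ca, TARGETS, pen=0.0) == 0.0

    def test_ten_percent_sl_error(self):
        sl, ca = perfect_biomarkers(TARGETS)
        vals = dict(sl.values)
        vals["Short"] = 4.14 * 1.1
        cost = recalibration_cost(BiomarkerSet("SL", vals), ca, TARGETS)
        assert cost == pytest.approx(0.01 / 11.0, rel=1e-9)

    def test_penalty_dominates_perfect_biomarkers(self):
        sl, ca = perfect_biomarkers(TARGETS)
        assert recalibration_cost(sl, ca, TARGETS, pen=1.0) >= 1.0

    def test_ca_outside_range_counts_via_range_distance(self):
        sl, ca = perfect_biomarkers(TARGETS)
        vals = dict(ca.values)
        vals["CaRes"] = 0.089 * 0.9
        cost = recalibration_cost(sl, BiomarkerSet("Ca", vals), TARGETS)
        assert cost == pytest.approx(0.01 / 11.0, rel=1e-9)

    def test_missing_biomarker_maps_to_sentinel(self):
        sl, ca = perfect_biomarkers(TARGETS)
        vals = dict(sl.values)
        vals["SLTR90"] = math.nan
        assert recalibration_cost(BiomarkerSet("SL", vals), ca, TARGETS) == COST_SENTINEL

    def test_order_invariance(self):
        sl, ca = perfect_biomarkers(TARGETS)
        vals = dict(sl.values)
        vals["Short"] *= 1.2
        vals["SLTP"] *= 0.9
        c1 = recalibration_cost(BiomarkerSet("SL", vals), ca, TARGETS)
        rev = BiomarkerSet("SL", dict(reversed(list(vals.items()))))
        assert recalibration_cost(rev, ca, TARGETS) == pytest.approx(c1)


class TestCaSensitivity:
    def test_half_maximal_point_matches_brute_force(self):
        params = rat_params()
        fit = ca_sensitivity(params)
        # brute force: bisect the analytic stress curve for half of Sa_max
        ca_grid = np.logspace(-2, 2, 20001)
        sa = np.array([steady_state_active_stress(params, c) for c in ca_grid])
        half = sa.max() / 2.0  # stress saturates at the top of the grid
        ca50_bf = ca_grid[int(np.argmin(np.abs(sa - half)))]
        assert fit.ca50_um == pytest.approx(ca50_bf, rel=0.05)
        assert 5.0 <= fit.pca50 <= 7.0

    def test_refit_reproduces_pca50(self):
        params = rat_params()
        a = ca_sensitivity(params)
        b = ca_sensitivity(params)
        assert a.pca50 == pytest.approx(b.pca50, abs=1e-4)

    def test_zero_stress_rejected(self):
        params = rat_params(Ca50ref=1e9)  # stress ~ 0 over the pCa grid
        with pytest.raises(RuntimeError):
            ca_sensitivity(params)


class TestIC50Short:
    def test_recovers_generating_ic50(self):
        concs = [0.1, 1.0, 10.0]
        effects = [-100.0 * c / (c + 1.0) for c in concs]  # IC50 = 1 uM, h = 1
        fit = ic50_short(effects, concs)
        assert not fit.censored
        assert fit.ic50_um == pytest.approx(1.0, rel=1e-3)

    def test_weak_effects_are_censored_at_top_concentration(self):
        fit = ic50_short([-2.0, -5.0, -10.0], [0.1, 1.0, 10.0])
        assert fit.censored
        assert fit.top_concentration_um == 10.0
        assert "> 10" in str(fit)

    def test_exact_half_maximum_at_interior_concentration(self):
        concs = [0.1, 1.0, 10.0, 100.0]
        effects = [-100.0 * c / (c + 1.0) for c in concs]
        fit = ic50_short(effects, concs)
        assert fit.ic50_um == pytest.approx(1.0, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ic50_short([-50.0, -60.0], [1.0, 10.0])


class TestRecalibrate:
    def test_recovers_single_free_parameter(self, desk_study):
        proto = StimulusProtocol(n_beats=40, dt_solver=0.05)
        truth = rat_params()
        res_truth = __import__("cardiotrans").models.run_paced(truth, None, proto)
        sl_t, ca_t = res_truth.biomarkers()
        targets = CalibrationTargets(
            sl_targets={k: sl_t[k] for k in
                        ("SLRes", "Short", "SLTP", "SLTR50", "SLTR90",
                         "dSLMaxC", "dSLMaxR")},
            ca_targets={k: (ca_t[k] * 0.97, ca_t[k] * 1.03) for k in
                        ("CaRes", "CaPeak", "CaTP", "CaTR50")},
        )
        start = truth.with_values(c_a=truth["c_a"])
        fit = recalibrate(start, ["c_a"], targets, proto, seed=5,
                          maxiter=12, popsize=8)
        assert fit.fitted_values["c_a"] == pytest.approx(truth["c_a"], rel=0.01)

    def test_degenerate_bounds_return_reference(self):
        proto = StimulusProtocol(n_beats=10, dt_solver=0.05)
        params = rat_params()
        fit = recalibrate(params, ["c_a"], TARGETS, proto,
                          bounds_rel=(1.0, 1.0 + 1e-12), seed=0,
                          maxiter=2, popsize=4)
        assert fit.fitted_values["c_a"] == pytest.approx(params["c_a"], rel=1e-6)

    def test_empty_free_list_rejected(self):
        with pytest.raises(ValueError):
            recalibrate(rat_params(), [], TARGETS)
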