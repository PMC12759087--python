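"""Cell-model contract: coupling primitives, scaling, paced runs."""

import numpy as np
import pytest

from cardiotrans.models import (
    StimulusProtocol,
    apply_scaling,
    calmodulin_buffer_factor,
    catrpn_dynamics,
    human_params,
    rat_params,
    run_paced,
)
from cardiotrans.models.simulate import limit_cycle_check


class TestCalmodulinBuffer:
    def test_no_buffer_gives_unity(self):
        assert calmodulin_buffer_factor(0.1, 0.0, 2.38) == 1.0

    def test_saturates_to_unity_at_high_ca(self):
        assert calmodulin_buffer_factor(1e9, 50.0, 2.38) == pytest.approx(1.0, abs=1e-6)

    def test_reference_value_in_mM(self):
        # CMDN 0.05 mM, K 0.00238 mM, Cai 0.0001 mM
        beta = calmodulin_buffer_factor(0.0001, 0.05, 0.00238)
        assert beta == pytest.approx(
            1.0 / (1.0 + 0.05 * 0.00238 / (0.0001 + 0.00238) ** 2), rel=1e-12
        )
        assert beta == pytest.approx(0.0492, abs=5e-4)

    def test_invalid_dissociation_constant(self):
        with pytest.raises(ValueError):
            calmodulin_buffer_factor(0.1, 50.0, 0.0)


class TestTroponinKinetics:
    def test_equilibrium_at_half_occupancy(self):
        rate, _ = catrpn_dynamics(1.6, 0.5, 0.06, 1.6, 2.0, 70.0)
        assert rate == pytest.approx(0.0, abs=1e-15)

    def test_pure_unbinding_at_zero_ca(self):
        rate, total = catrpn_dynamics(0.0, 0.2, 0.06, 1.6, 2.0, 70.0)
        assert rate == pytest.approx(-0.06 * 0.2)
        assert total == pytest.approx(70.0 * rate)

    @pytest.mark.parametrize("rho", [0.25, 1.0, 3.0])
    def test_analytic_steady_state(self, rho):
        n = 2.0
        ca50 = 1.6
        occ_star = rho**n / (1.0 + rho**n)
        rate, _ = catrpn_dynamics(rho * ca50, occ_star, 0.06, ca50, n, 70.0)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_occupancy_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            catrpn_dynamics(1.0, 1.2, 0.06, 1.6, 2.0, 70.0)


class TestScaling:
    def test_empty_scaling_is_identity(self):
        p = rat_params()
        assert apply_scaling(p, {}) is p

    def test_serca_halving_touches_only_serca(self):
        p = rat_params()
        q = apply_scaling(p, {"SERCA2": 0.5})
        assert q["V_SERCA"] == pytest.approx(0.5 * p["V_SERCA"])
        for name, v in p.values.items():
            if name != "V_SERCA":
                assert q[name] == v

    def test_herg_block_refused_in_rat(self):
        with pytest.raises(ValueError, match="not present"):
            apply_scaling(rat_params(), {"hERG": 0.5})

    def test_herg_block_accepted_in_human(self):
        q = apply_scaling(human_params(), {"hERG": 0.5})
        assert q["g_Kr"] == pytest.approx(0.5 * human_params()["g_Kr"])

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            apply_scaling(rat_params(), {"SERCA2": 1.5})


class TestParamsSerialisation:
    @pytest.mark.parametrize("make", [rat_params, human_params])
    def test_json_round_trip(self, make):
        p = make()
        q = type(p).from_json(p.to_json())
        assert q.species == p.species
        assert q.values == p.values
        assert q.digest() == p.digest()

    def test_species_absent_parameter_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            rat_params(g_Kr=0.1)


class TestStimulusProtocol:
    def test_amplitude_preserves_time_integral(self):
        p = StimulusProtocol(duration=1.0)
        assert p.amplitude * p.duration == pytest.approx(50.0)
        q = p.with_(duration=2.0)
        assert q.amplitude * q.duration == pytest.approx(50.0)
        assert q.amplitude == pytest.approx(25.0)

    def test_solver_step_must_not_exceed_output_step(self):
        with pytest.raises(ValueError):
            StimulusProtocol(dt_solver=2.0, dt_output=1.0)


SHORT_PROTO = StimulusProtocol(n_beats=10, dt_solver=0.05)


class TestRunPaced:
    def test_zero_stimulus_stays_at_rest(self):
        proto = StimulusProtocol(n_beats=5, dt_solver=0.05, integral=1e-9)
        res = run_paced(rat_params(), None, proto)
        sl, _ = res.biomarkers()
        assert sl["Short"] < 0.05  # essentially no contraction

    def test_bit_reproducible(self):
        a = run_paced(rat_params(), None, SHORT_PROTO)
        b = run_paced(rat_params(), None, SHORT_PROTO)
        np.testing.assert_array_equal(a.sl_transient.value, b.sl_transient.value)
        np.testing.assert_array_equal(a.final_state, b.final_state)

    @pytest.mark.parametrize("make", [rat_params, human_params])
    def test_state_validity_on_output_grid(self, make):
        res = run_paced(make(), None, SHORT_PROTO)
        assert np.all(res.cai_transient.value > 0)
        assert np.all(res.sl_transient.value > 0)
        # gating and occupancy stay inside [0, 1] in the final state
        gates = res.final_state[4:14]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
        assert 0.0 <= res.final_state[14] <= 1.0

    def test_output_grids_cover_all_beats(self):
        res = run_paced(rat_params(), None, SHORT_PROTO)
        assert res.sl_transient.time.shape == res.cai_transient.time.shape
        assert len(res.stimulus_times) == SHORT_PROTO.n_beats
        assert res.sl_transient.time[-1] == pytest.approx(
            SHORT_PROTO.period * SHORT_PROTO.n_beats - SHORT_PROTO.dt_output
        )

    def test_serca_block_reduces_ca_amplitude(self, desk_study):
        for species in ("rat", "human"):
            _, base = desk_study.baseline_biomarkers(species)
            drug = desk_study.drugged_run(species, {"SERCA2": 0.6})
            _, cab = drug.biomarkers()
            amp = "CaAmp"
            assert cab[amp] < base[amp]

    def test_solver_refinement_consistency(self):
        fine = run_paced(rat_params(), None, SHORT_PROTO.with_(dt_solver=0.01))
        coarse = run_paced(rat_params(), None, SHORT_PROTO)
        slf, caf = fine.biomarkers()
        slc, cac = coarse.biomarkers()
        assert slc["Short"] == pytest.approx(slf["Short"], rel=0.02)
        assert cac["CaTR50"] == pytest.approx(caf["CaTR50"], rel=0.02)


class TestLimitCycle:
    def test_identical_lengths_give_zero_change(self):
        ch = limit_cycle_check(rat_params(), None, SHORT_PROTO, SHORT_PROTO.n_beats)
        assert ch["Cai_peak"] == 0.0
        assert ch["SL_peak"] == 0.0

    @pytest.mark.parametrize("make", [rat_params, human_params])
    def test_hundred_beats_near_limit_cycle(self, make):
        proto = StimulusProtocol(n_beats=100, dt_solver=0.05)
        ch = limit_cycle_check(make(), None, proto, 300)
        assert abs(ch["Cai_peak"]) < 5.0
        assert abs(ch["SL_peak"]) < 5.0
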