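"""Biomarker extraction, abnormality screening and drug-effect arithmetic."""

import math

import numpy as np
import pytest

from cardiotrans.synthetic import AnalyticWaveformSpec, generate_waveform
from cardiotrans.transients import (
    BiomarkerSet,
    Transient,
    classify_effect,
    detect_abnormalities,
    drug_effect,
    extract_biomarkers,
)

# fine output grid keeps the oracle comparison within one interpolation step
DT = 0.5


def waveform(**kw):
    kw.setdefault("dt", DT)
    kw.setdefault("n_beats", 2)
    return generate_waveform(AnalyticWaveformSpec(**kw))


class TestBiomarkerOracle:
    @pytest.mark.parametrize("shape", ["triangle", "raised_cosine"])
    @pytest.mark.parametrize(
        "kind, rest, dev, tp, rd",
        [
            ("SL", 1.80, -0.09, 50.0, 100.0),
            ("SL", 1.90, -0.04, 70.0, 160.0),
            ("Ca", 0.10, 1.00, 20.0, 100.0),
            ("Ca", 0.15, 0.35, 60.0, 300.0),
        ],
    )
    def test_matches_closed_form(self, shape, kind, rest, dev, tp, rd):
        tr, expected, _ = waveform(
            kind=kind, rest=rest, peak_dev=dev, time_to_peak=tp,
            return_duration=rd, shape=shape,
        )
        got = extract_biomarkers(tr)
        for name in expected.names:
            exp = expected[name]
            val = got[name]
            if name in ("SLRes", "CaRes"):
                assert val == pytest.approx(exp, rel=1e-9)
            elif name in ("Short", "CaAmp"):
                assert val == pytest.approx(exp, rel=2e-2)
            elif name.startswith(("SLT", "CaT")):
                assert val == pytest.approx(exp, abs=DT)  # one grid step
            else:  # extreme rates; sampled extremum of a smooth slope
                assert val == pytest.approx(exp, rel=5e-2)

    def test_triangle_reference_beat(self):
        # rest 1.80 um, linear dip of 0.09 um over 50 ms, recovery in 100 ms
        tr, _, _ = waveform(
            kind="SL", rest=1.80, peak_dev=-0.09, time_to_peak=50.0,
            return_duration=100.0,
        )
        bm = extract_biomarkers(tr)
        assert bm["SLRes"] == pytest.approx(1.80)
        assert bm["Short"] == pytest.approx(5.0, rel=1e-2)
        assert bm["SLTP"] == pytest.approx(50.0, abs=DT)
        assert bm["SLTR50"] == pytest.approx(50.0, abs=DT)
        assert bm["SLTR90"] == pytest.approx(90.0, abs=DT)
        assert bm["dSLMaxC"] == pytest.approx(-0.0018, rel=5e-2)
        assert bm["dSLMaxR"] == pytest.approx(0.0009, rel=5e-2)

    def test_flat_transient_has_zero_amplitude_and_missing_times(self):
        time = np.arange(0, 2000.0, 1.0)
        tr = Transient(time, np.full_like(time, 1.85), "SL", [0.0, 1000.0], 1.0)
        bm = extract_biomarkers(tr)
        assert bm["Short"] == 0.0
        assert bm["dSLMaxC"] == 0.0
        assert math.isnan(bm["SLTR50"])

    def test_time_shift_invariance(self):
        tr, _, _ = waveform(
            kind="Ca", rest=0.1, peak_dev=1.0, time_to_peak=20.0,
            return_duration=100.0,
        )
        shifted = tr.shifted(137.0)
        a = extract_biomarkers(tr)
        b = extract_biomarkers(shifted)
        for name in a.names:
            assert b[name] == pytest.approx(a[name], nan_ok=True)

    def test_ca_scaling_scales_amplitudes_not_times(self):
        tr, _, _ = waveform(
            kind="Ca", rest=0.1, peak_dev=1.0, time_to_peak=20.0,
            return_duration=100.0,
        )
        k = 2.5
        scaled = Transient(tr.time, tr.value * k, "Ca", tr.stimulus_times,
                           tr.pacing_frequency)
        a, b = extract_biomarkers(tr), extract_biomarkers(scaled)
        for name in ("CaRes", "CaAmp", "dCaMax", "dCaMin"):
            assert b[name] == pytest.approx(k * a[name], rel=1e-9)
        for name in ("CaTP", "CaTR50", "CaTR90"):
            assert b[name] == pytest.approx(a[name], rel=1e-9)

    def test_sl_offset_changes_short_but_no_time_biomarker(self):
        tr, _, _ = waveform(
            kind="SL", rest=1.80, peak_dev=-0.09, time_to_peak=50.0,
            return_duration=100.0,
        )
        off = Transient(tr.time, tr.value + 0.1, "SL", tr.stimulus_times,
                        tr.pacing_frequency)
        a, b = extract_biomarkers(tr), extract_biomarkers(off)
        assert b["SLRes"] == pytest.approx(a["SLRes"] + 0.1)
        assert b["Short"] < a["Short"]
        for name in ("SLTP", "SLTR50", "SLTR90"):
            assert b[name] == pytest.approx(a[name])


class TestAbnormalities:
    def test_equal_amplitudes_no_alternans(self):
        tr, _, _ = waveform(kind="SL", rest=1.8, peak_dev=-0.10,
                            time_to_peak=50.0, return_duration=100.0)
        assert not detect_abnormalities(tr).alternans

    def test_ratio_above_threshold_flags_alternans(self):
        # amplitudes 0.09 vs 0.10: ratio ~1.111 > 1.1
        tr, _, flags = waveform(kind="SL", rest=1.8, peak_dev=-0.09,
                                time_to_peak=50.0, return_duration=100.0,
                                alternans_ratio=10.0 / 9.0)
        assert flags.alternans
        assert detect_abnormalities(tr).alternans

    def test_ratio_exactly_at_threshold_is_not_alternans(self):
        tr, _, flags = waveform(kind="SL", rest=1.8, peak_dev=-0.10,
                                time_to_peak=50.0, return_duration=100.0,
                                alternans_ratio=1.1)
        assert not flags.alternans
        assert not detect_abnormalities(tr).alternans

    @pytest.mark.parametrize(
        "kind, rate, where, attr",
        [
            # rates are net of the triangle's own slope (SL falls at -0.0018
            # pre-peak and rises at +0.0009 post-peak; Ca mirrors)
            ("SL", +0.0040, "pre", "fluctuation_pre_peak"),
            ("SL", -0.0025, "post", "fluctuation_post_peak"),
            ("Ca", -0.0300, "pre", "fluctuation_pre_peak"),
            ("Ca", +0.0120, "post", "fluctuation_post_peak"),
        ],
    )
    def test_injected_fluctuations_detected(self, kind, rate, where, attr):
        # excursions stay shallow enough not to relocate the beat extremum
        dev = -0.09 if kind == "SL" else 1.0
        rest = 1.8 if kind == "SL" else 0.1
        t0 = 10.0 if where == "pre" else (100.0 if kind == "SL" else 60.0)
        tr, _, flags = waveform(kind=kind, rest=rest, peak_dev=dev,
                                time_to_peak=50.0, return_duration=100.0,
                                fluctuation=(t0, rate, 20.0))
        assert getattr(flags, attr)
        assert getattr(detect_abnormalities(tr), attr)

    def test_wrong_sign_excursion_not_flagged(self):
        # a *negative* pre-peak SL rate is the normal contraction direction
        tr, _, flags = waveform(kind="SL", rest=1.8, peak_dev=-0.09,
                                time_to_peak=50.0, return_duration=100.0,
                                fluctuation=(10.0, -0.002, 20.0))
        assert not flags.fluctuation_pre_peak
        got = detect_abnormalities(tr)
        assert not got.fluctuation_pre_peak

    def test_single_beat_rejected(self):
        tr, _, _ = waveform(kind="SL", rest=1.8, peak_dev=-0.09,
                            time_to_peak=50.0, return_duration=100.0, n_beats=1)
        with pytest.raises(ValueError):
            detect_abnormalities(tr)


class TestDrugEffect:
    def sl(self, short):
        return BiomarkerSet("SL", {"SLRes": 1.8, "Short": short, "SLTP": 60.0,
                                   "SLTR50": 40.0, "SLTR90": 90.0,
                                   "dSLMaxC": -2e-3, "dSLMaxR": 1e-3})

    def test_quarter_reduction(self):
        eff = drug_effect(self.sl(4.0), self.sl(3.0))
        assert eff["Short"] == pytest.approx(-25.0)

    def test_identity_gives_zero(self):
        eff = drug_effect(self.sl(4.0), self.sl(4.0))
        assert all(v == 0.0 for v in eff.values())

    def test_sixfold_increase_hits_inclusion_boundary(self):
        eff = drug_effect(self.sl(4.0), self.sl(24.0))
        assert eff["Short"] == pytest.approx(500.0)

    def test_zero_baseline_yields_nan_not_error(self):
        eff = drug_effect(self.sl(0.0), self.sl(3.0))
        assert math.isnan(eff["Short"])


class TestClassification:
    @pytest.mark.parametrize(
        "scheme, effect, label",
        [
            ("human", -25.0, "negative"),
            ("human", 10.0, "positive"),
            ("human", -10.0, "absent"),
            ("human", 9.99, "absent"),
            ("rat_sim", 5.0, "positive"),
            ("rat_sim", -5.0, "negative"),
            ("rat_sim", 4.9, "absent"),
            ("rat_sim", -4.9, "absent"),
        ],
    )
    def test_threshold_rules(self, scheme, effect, label):
        assert classify_effect(effect, scheme) == label

    def test_every_finite_effect_gets_exactly_one_label(self):
        for eff in np.linspace(-200, 600, 401):
            assert classify_effect(float(eff), "human") in (
                "positive", "negative", "absent",
            )

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            classify_effect(0.0, "dog")
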