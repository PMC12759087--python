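"""Shared test constructions: analytic simulation results and targets."""

import numpy as np

from cardiotrans.calibration import CalibrationTargets
from cardiotrans.models import rat_params
from cardiotrans.models.simulate import SimulationResult
from cardiotrans.synthetic import AnalyticWaveformSpec, generate_waveform
from cardiotrans.transients import BiomarkerSet


def synthetic_result(sl_kw=None, ca_kw=None) -> SimulationResult:
    """Two-beat analytic run wrapped as a SimulationResult."""
    sl_spec = AnalyticWaveformSpec(
        "SL", 1.80, -0.09, 50.0, 100.0, dt=0.5, n_beats=2, **(sl_kw or {})
    )
    ca_spec = AnalyticWaveformSpec(
        "Ca", 0.10, 1.00, 50.0, 100.0, dt=0.5, n_beats=2, **(ca_kw or {})
    )
    sl_tr, _, _ = generate_waveform(sl_spec)
    ca_tr, _, _ = generate_waveform(ca_spec)
    return SimulationResult(
        sl_transient=sl_tr,
        cai_transient=ca_tr,
        v_time=sl_tr.time,
        v=np.full_like(sl_tr.time, -80.0),
        stimulus_times=sl_tr.stimulus_times,
        params_used=rat_params(),
        scaling_used={},
        final_state=np.zeros(17),
    )


TARGETS = CalibrationTargets(
    sl_targets={"SLRes": 1.878, "Short": 4.14, "SLTP": 61.0, "SLTR50": 44.0,
                "SLTR90": 80.0, "dSLMaxC": -2.08e-3, "dSLMaxR": 1.37e-3},
    ca_targets={"CaRes": (0.089, 0.121), "CaPeak": (1.0, 3.0),
                "CaTP": (21.0, 39.0), "CaTR50": (67.0, 97.0)},
)


def perfect_biomarkers(targets: CalibrationTargets):
    sl = BiomarkerSet("SL", dict(targets.sl_targets))
    ca = BiomarkerSet(
        "Ca", {k: 0.5 * (lo + hi) for k, (lo, hi) in targets.ca_targets.items()}
    )
    return sl, ca
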