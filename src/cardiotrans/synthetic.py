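"""Synthetic fixtures: analytic waveforms and model-generated drug datasets.

Two generators live here.  ``generate_waveform`` builds piecewise-analytic
beats (triangle or raised-cosine) whose biomarkers have closed forms, so the
biomarker extractor can be tested against exact expectations; alternans and
localised fluctuations can be injected with known outcomes.
``generate_drug_effect_dataset`` runs the cell models before/after a virtual
drug and returns paired rat and human drug-effect tables together with the
generating (ground-truth) potencies, which is the raw material for the
identifiability analysis and the synthetic translation evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .transients import AbnormalityFlags, BiomarkerSet, DrugEffectTable, Transient

__all__ = ["AnalyticWaveformSpec", "generate_waveform", "generate_drug_effect_dataset"]


@dataclass(frozen=True)
class AnalyticWaveformSpec:
    """A beat with closed-form biomarkers.

    The beat rests at ``rest``, deviates by ``peak_dev`` (negative for SL
    shortening, positive for a Ca transient) reaching the peak at
    ``time_to_peak`` ms after the stimulus, and returns linearly
    (``triangle``) or smoothly (``raised_cosine``) over ``return_duration``
    ms.  ``alternans_ratio`` scales every second beat's amplitude;
    ``fluctuation`` injects a short linear excursion of a given rate.
    """

    kind: Literal["SL", "Ca"]
    rest: float
    peak_dev: float
    time_to_peak: float  # ms
    return_duration: float  # ms
    shape: Literal["triangle", "raised_cosine"] = "triangle"
    period: float = 1000.0  # ms
    n_beats: int = 2
    dt: float = 1.0  # ms
    alternans_ratio: float = 1.0  # amplitude ratio of odd beats
    # (t_start_ms within beat, rate units/ms, duration_ms) or None
    fluctuation: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.time_to_peak + self.return_duration > self.period:
            raise ValueError("beat phases must fit within the period")
        if self.time_to_peak <= 0 or self.return_duration <= 0:
            raise ValueError("durations must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats >= 1 required")
        if self.kind == "SL" and self.peak_dev >= 0:
            raise ValueError("SL beats shorten: peak_dev must be negative")
        if self.kind == "Ca" and self.peak_dev <= 0:
            raise ValueError("Ca beats rise: peak_dev must be positive")
        if self.fluctuation is not None:
            if self.shape != "triangle":
                raise ValueError(
                    "fluctuation injection has closed-form expectations only "
                    "for the triangle shape"
                )
            t0, _, dur = self.fluctuation
            tp, rd = self.time_to_peak, self.return_duration
            if not (t0 + dur <= tp or (tp < t0 and t0 + dur <= tp + rd)):
                raise ValueError(
                    "fluctuation window must lie within the rising or the "
                    "falling phase"
                )


def _beat_value(spec: AnalyticWaveformSpec, tau: float, dev: float) -> float:
    """Waveform value at time ``tau`` after the stimulus, amplitude ``dev``."""
    tp, rd = spec.time_to_peak, spec.return_duration
    if tau < 0 or tau >= tp + rd:
        return spec.rest
    if spec.shape == "triangle":
        if tau <= tp:
            return spec.rest + dev * tau / tp
        return spec.rest + dev * (1.0 - (tau - tp) / rd)
    # raised cosine: smooth rise and fall, C1 at the peak
    if tau <= tp:
        return spec.rest + dev * 0.5 * (1.0 - math.cos(math.pi * tau / tp))
    return spec.rest + dev * 0.5 * (1.0 + math.cos(math.pi * (tau - tp) / rd))


def _expected_biomarkers(spec: AnalyticWaveformSpec, dev: float) -> BiomarkerSet:
    """Closed-form biomarkers of the final beat (amplitude ``dev``)."""
    rest = spec.rest
    amp = abs(dev)
    tp, rd = spec.time_to_peak, spec.return_duration
    if spec.shape == "triangle":
        tr50, tr70, tr90 = 0.5 * rd, 0.7 * rd, 0.9 * rd
        rise_rate = amp / tp
        fall_rate = amp / rd
    else:
        # recovery of fraction x after the peak: tau = rd/pi * arccos(1-2x)
        tr50 = rd / math.pi * math.acos(0.0)
        tr70 = rd / math.pi * math.acos(-0.4)
        tr90 = rd / math.pi * math.acos(-0.8)
        rise_rate = amp * math.pi / (2.0 * tp)  # max slope of the raised cosine
        fall_rate = amp * math.pi / (2.0 * rd)
    if spec.kind == "SL":
        vals = {
            "SLRes": rest,
            "Short": 100.0 * amp / rest,
            "SLTP": tp,
            "SLTR50": tr50,
            "SLTR90": tr90,
            "dSLMaxC": -rise_rate,
            "dSLMaxR": fall_rate,
            "SLTD70": tp + tr70,
            "SLTD90": tp + tr90,
        }
    else:
        vals = {
            "CaRes": rest,
            "CaAmp": amp,
            "CaPeak": rest + amp,
            "CaTP": tp,
            "CaTR50": tr50,
            "CaTR90": tr90,
            "dCaMax": rise_rate,
            "dCaMin": -fall_rate,
        }
    return BiomarkerSet(spec.kind, vals)


def generate_waveform(
    spec: AnalyticWaveformSpec,
) -> tuple[Transient, BiomarkerSet, AbnormalityFlags]:
    """Sample the waveform and return its exact expected biomarkers and flags.

    The expected biomarkers refer to the final beat.  The expected
    abnormality flags follow directly from the spec: alternans iff the
    injected amplitude ratio exceeds 1.1, fluctuation flags iff an injected
    excursion violates the signed-rate threshold in its window.
    """
    n = int(round(spec.period * spec.n_beats / spec.dt))
    time = np.arange(n) * spec.dt
    stim = np.arange(spec.n_beats) * spec.period
    value = np.empty(n)
    for i, t in enumerate(time):
        b = int(t // spec.period)
        dev = spec.peak_dev * (spec.alternans_ratio if b % 2 == 1 else 1.0)
        value[i] = _beat_value(spec, t - b * spec.period, dev)

    if spec.fluctuation is not None:
        t0, rate, dur = spec.fluctuation
        # inject into every beat so both screened beats carry it
        for b in range(spec.n_beats):
            tau = time - b * spec.period
            ramp = (tau >= t0) & (tau < t0 + dur)
            value[ramp] += rate * (tau[ramp] - t0)

    final_dev = spec.peak_dev * (
        spec.alternans_ratio if (spec.n_beats - 1) % 2 == 1 else 1.0
    )
    expected = _expected_biomarkers(spec, final_dev)

    ratio = max(abs(spec.alternans_ratio), 1e-12)
    ratio = max(ratio, 1.0 / ratio)
    exp_alternans = spec.n_beats >= 2 and ratio > 1.1
    exp_pre = exp_post = False
    if spec.fluctuation is not None:
        # the injected ramp rides on the beat's own slope: the screened rate
        # is the net of the two (triangle slopes are constant per phase)
        t0, rate, dur = spec.fluctuation
        pre_window = t0 + dur <= spec.time_to_peak
        base = (
            spec.peak_dev / spec.time_to_peak
            if pre_window
            else -spec.peak_dev / spec.return_duration
        )
        net = rate + base
        sign_bad_pre = net > 1e-3 if spec.kind == "SL" else net < -1e-3
        sign_bad_post = net < -1e-3 if spec.kind == "SL" else net > 1e-3
        if pre_window:
            exp_pre = bool(sign_bad_pre)
        else:
            exp_post = bool(sign_bad_post)
    flags = AbnormalityFlags(bool(exp_alternans), exp_pre, exp_post)

    tr = Transient(time, value, spec.kind, stim, 1000.0 / spec.period)
    return tr, expected, flags


def generate_drug_effect_dataset(
    drug,
    concentrations_um: Sequence[float],
    study=None,
) -> dict:
    """Simulate one virtual drug in both species and package the effects.

    Returns a dict with keys ``rat`` and ``human`` (DrugEffectTable),
    ``truth`` (the generating DrugSpec), and ``abnormal`` (per species, the
    concentrations whose transients were flagged).  ``study`` is a
    ``cardiotrans.models.DrugStudy`` (defaults are created if omitted);
    passing one in lets a batch reuse the cached baseline limit cycle.
    """
    from .models import DrugStudy

    if study is None:
        study = DrugStudy.desk()
    out = {"truth": drug, "abnormal": {}}
    for species in ("rat", "human"):
        effects, abnormal = study.drug_effects(species, drug, concentrations_um)
        out[species] = DrugEffectTable.from_effects(effects, species=species)
        out["abnormal"][species] = abnormal
    return out
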