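"""Model recalibration, penalties, Ca2+ sensitivity and IC50-Short.

The recalibration cost compares simulated final-beat biomarkers with
experimental targets: 7 sarcomere-length biomarkers enter as squared
relative errors against medians, 4 intracellular-[Ca2+] biomarkers as
squared relative distances to a mean +/- SD range, jointly weighted 1/11,
plus a transient penalty ``Pen`` that punishes alternans (beat-amplitude
ratio terms, coefficient c1) and fluctuations (wrong-signed rate terms,
coefficient c2).  The coefficients are chosen so that reaching an
abnormality threshold contributes at least 1 during recalibration and at
least 100 during potency inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .models import CellModelParams, StimulusProtocol, run_paced
from .models.simulate import SimulationError, SimulationResult
from .transients import BiomarkerSet, Transient

__all__ = [
    "PenaltyConfig",
    "RECALIBRATION_PENALTY",
    "INFERENCE_PENALTY",
    "CalibrationTargets",
    "RAT_TARGETS_TABLE",
    "HUMAN_TARGETS_TABLE",
    "RAT_SL_RANGES",
    "HUMAN_SL_RANGES",
    "RAT_APD_RANGES",
    "HUMAN_APD_RANGES",
    "COST_SENTINEL",
    "range_distance",
    "transient_penalty",
    "recalibration_cost",
    "recalibrate",
    "ca_sensitivity",
    "ic50_short",
]

#: Large finite cost assigned to infeasible candidates during optimisation.
COST_SENTINEL = 1.0e6


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty coefficients and abnormality thresholds.

    ``amplitude_form`` selects the alternans amplitude-ratio term:
    'min_over_max' implements (minAmp/maxAmp - 1)^2 (the literal published
    formula; at the 1.1 threshold with c1 = 100 it contributes ~0.83),
    'max_over_min' the (maxAmp/minAmp - 1)^2 variant whose threshold
    contribution is exactly c1/100.
    """

    c1: float = 1.0e2
    c2: float = 1.0e6
    alternans_ratio: float = 1.1
    fluctuation_rate: float = 1.0e-3
    amplitude_form: str = "min_over_max"

    def __post_init__(self) -> None:
        if self.amplitude_form not in ("min_over_max", "max_over_min"):
            raise ValueError("amplitude_form must be 'min_over_max' or 'max_over_min'")


RECALIBRATION_PENALTY = PenaltyConfig(c1=1.0e2, c2=1.0e6)
INFERENCE_PENALTY = PenaltyConfig(c1=1.0e4, c2=1.0e8)


def range_distance(value: float, lb: float, ub: float) -> float:
    """Signed relative distance to a target range; 0 inside.

    Below the range: (v - lb)/lb; above: (v - ub)/ub.  The caller squares
    the result.
    """
    if not lb < ub:
        raise ValueError("range must satisfy lb < ub")
    if lb == 0.0 or ub == 0.0:
        raise ValueError("zero range bound cannot serve as a denominator")
    if value < lb:
        return (value - lb) / lb
    if value > ub:
        return (value - ub) / ub
    return 0.0


def _beat_windows(tr: Transient, stim_index: int):
    """(amplitude, pre-peak rates, post-peak rates) of one beat."""
    from .transients import _beat_amp_and_windows

    return _beat_amp_and_windows(tr, stim_index)


def transient_penalty(
    result: SimulationResult, cfg: PenaltyConfig = RECALIBRATION_PENALTY
) -> float:
    """Penalty of one paced run, Pen >= 0, 0 for a clean periodic result.

    Amplitude-ratio terms (c1) compare the last two beats of the SL and Ca
    transients; rate terms (c2) penalise positive pre-peak / negative
    post-peak SL rates and negative pre-peak / positive post-peak Ca rates,
    with the non-violating sign clipped to zero.
    """
    if len(result.stimulus_times) < 2:
        raise ValueError("penalty requires at least 2 beats")
    i2 = len(result.stimulus_times) - 1
    pen = 0.0
    for tr in (result.sl_transient, result.cai_transient):
        a1, pre1, post1 = _beat_windows(tr, i2 - 1)
        a2, pre2, post2 = _beat_windows(tr, i2)
        lo, hi = sorted((a1, a2))
        if hi <= 0.0:
            ratio_term = 0.0
        elif cfg.amplitude_form == "min_over_max":
            ratio_term = (lo / hi - 1.0) ** 2
        else:
            ratio_term = (hi / max(lo, 1e-12) - 1.0) ** 2
        pen += cfg.c1 * ratio_term

        pre = np.concatenate([w for w in (pre1, pre2) if w.size]) if (pre1.size or pre2.size) else np.zeros(1)
        post = np.concatenate([w for w in (post1, post2) if w.size]) if (post1.size or post2.size) else np.zeros(1)
        if tr.kind == "SL":
            pen += cfg.c2 * max(0.0, float(np.max(pre))) ** 2
            pen += cfg.c2 * min(0.0, float(np.min(post))) ** 2
        else:
            pen += cfg.c2 * min(0.0, float(np.min(pre))) ** 2
            pen += cfg.c2 * max(0.0, float(np.max(post))) ** 2
    return pen


@dataclass(frozen=True)
class CalibrationTargets:
    """7 SL biomarker medians and 4 Ca biomarker mean +/- SD ranges."""

    sl_targets: Mapping[str, float]
    ca_targets: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.sl_targets) != 7:
            raise ValueError("exactly 7 SL biomarker targets required")
        if len(self.ca_targets) != 4:
            raise ValueError("exactly 4 Ca biomarker targets required")
        for name, (lb, ub) in self.ca_targets.items():
            if not lb < ub:
                raise ValueError(f"Ca target {name}: lb < ub required")
        for name, v in self.sl_targets.items():
            if v == 0.0:
                raise ValueError(f"SL target {name} may not be zero")


def _pm(mean: float, sd: float) -> tuple[float, float]:
    return (mean - sd, mean + sd)


#: Experimental rat targets (SL medians; Ca mean +/- SD).
RAT_TARGETS_TABLE = CalibrationTargets(
    sl_targets={
        "SLRes": 1.878,
        "Short": 4.14,
        "SLTP": 61.0,
        "SLTR50": 44.0,
        "SLTR90": 80.0,
        "dSLMaxC": -2.08e-3,
        "dSLMaxR": 1.37e-3,
    },
    ca_targets={
        "CaRes": _pm(0.105, 0.016),
        "CaPeak": _pm(2.0, 1.0),
        "CaTP": _pm(30.0, 9.0),
        "CaTR50": _pm(82.0, 15.0),
    },
)

#: Experimental human targets (SL medians; Ca mean +/- SD).
HUMAN_TARGETS_TABLE = CalibrationTargets(
    sl_targets={
        "SLRes": 1.790,
        "Short": 3.79,
        "SLTP": 162.0,
        "SLTD70": 251.0,
        "SLTD90": 314.0,
        "dSLMaxC": -0.80e-3,
        "dSLMaxR": 0.82e-3,
    },
    ca_targets={
        "CaRes": _pm(0.14, 0.01),
        "CaAmp": _pm(0.35, 0.02),
        "CaTP": _pm(50.0, 10.0),
        "CaTR90": _pm(375.0, 40.0),
    },
)

#: Experimental min-max ranges of the SL biomarkers (model contract).
RAT_SL_RANGES = {
    "SLRes": (1.794, 1.970),
    "Short": (1.00, 15.07),
    "SLTP": (41.0, 97.0),
    "SLTR50": (19.0, 93.0),
    "SLTR90": (40.0, 191.0),
    "dSLMaxC": (-6.03e-3, -0.56e-3),
    "dSLMaxR": (0.29e-3, 7.27e-3),
}

HUMAN_SL_RANGES = {
    "SLRes": (1.490, 1.960),
    "Short": (1.82, 12.40),
    "SLTP": (101.0, 341.0),
    "SLTD70": (147.0, 560.0),
    "SLTD90": (189.0, 693.0),
    "dSLMaxC": (-2.21e-3, -0.29e-3),
    "dSLMaxR": (0.26e-3, 2.99e-3),
}

#: Experimental action-potential duration ranges (rat: mean +/- SD).
RAT_APD_RANGES = {"APD50": _pm(10.07, 1.72), "APD90": _pm(43.41, 7.08)}
HUMAN_APD_RANGES = {"APD50": (106.6, 349.4), "APD90": (178.1, 442.7)}


def recalibration_cost(
    sl: BiomarkerSet,
    ca: BiomarkerSet,
    targets: CalibrationTargets,
    pen: float = 0.0,
) -> float:
    """Cost = (1/11) * [sum sq. rel. SL errors + sum sq. range distances] + Pen.

    Zero exactly when every SL biomarker matches its median, every Ca
    biomarker lies inside its range and the penalty vanishes.  A missing
    simulated biomarker yields the large-but-finite cost sentinel so a
    population optimiser can continue.
    """
    total = 0.0
    for name, target in targets.sl_targets.items():
        v = sl.get(name)
        if not math.isfinite(v):
            return COST_SENTINEL
        total += ((v - target) / target) ** 2
    for name, (lb, ub) in targets.ca_targets.items():
        v = ca.get(name)
        if not math.isfinite(v):
            return COST_SENTINEL
        total += range_distance(v, lb, ub) ** 2
    return total / 11.0 + pen


#: Differential-evolution settings used for recalibration and inference.
DE_SETTINGS = dict(strategy="best1bin", recombination=0.7, mutation=(0.5, 1.0), tol=0.01)


@dataclass
class RecalibrationResult:
    params: CellModelParams
    cost: float
    free_names: tuple[str, ...]
    fitted_values: dict[str, float]
    n_evaluations: int
    trace: list[float] = field(default_factory=list)


def recalibrate(
    params: CellModelParams,
    free_names: Sequence[str],
    targets: CalibrationTargets,
    protocol: StimulusProtocol = StimulusProtocol(),
    bounds_rel: tuple[float, float] = (0.5, 1.5),
    penalty: PenaltyConfig = RECALIBRATION_PENALTY,
    seed: int = 0,
    maxiter: int = 30,
    popsize: int = 15,
) -> RecalibrationResult:
    """Fit free parameters to biomarker targets by differential evolution.

    Bounds default to 50-150 % of each parameter's reference value; the
    optimisation runs once (restart externally if desired) and candidate
    failures map to the cost sentinel rather than exceptions.
    """
    free_names = tuple(free_names)
    if not free_names:
        raise ValueError("free-parameter list must be non-empty")
    ref = np.array([params[n] for n in free_names])
    bounds = [
        tuple(sorted((bounds_rel[0] * r, bounds_rel[1] * r))) for r in ref
    ]
    trace: list[float] = []

    def cost_fn(x: np.ndarray) -> float:
        cand = params.with_values(**dict(zip(free_names, map(float, x))))
        try:
            res = run_paced(cand, None, protocol)
            slb, cab = res.biomarkers()
            pen = transient_penalty(res, penalty)
            c = recalibration_cost(slb, cab, targets, pen)
        except (SimulationError, ValueError):
            c = COST_SENTINEL
        trace.append(c)
        return c

    opt = differential_evolution(
        cost_fn,
        bounds,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        init="latinhypercube",
        polish=False,
        **DE_SETTINGS,
    )
    if not np.isfinite(opt.fun):
        raise RuntimeError(f"recalibration produced non-finite cost: {opt}")
    fitted = dict(zip(free_names, map(float, opt.x)))
    return RecalibrationResult(
        params=params.with_values(**fitted),
        cost=float(opt.fun),
        free_names=free_names,
        fitted_values=fitted,
        n_evaluations=len(trace),
        trace=trace,
    )


# -- Ca2+ sensitivity ---------------------------------------------------------

def steady_state_active_stress(params: CellModelParams, cai_um: float) -> float:
    """Normalised isometric active stress at clamped Ca and lambda = 1."""
    if cai_um < 0:
        raise ValueError("Cai must be >= 0")
    rho = cai_um / params["Ca50ref"]
    catrpn = rho ** params["nTRPN"] / (1.0 + rho ** params["nTRPN"])
    return catrpn ** params["n_xb"]


@dataclass(frozen=True)
class CaSensitivity:
    pca50: float
    ca50_um: float
    hill: float
    samax: float


def ca_sensitivity(params: CellModelParams) -> CaSensitivity:
    """pCa50 from a Hill fit of steady-state isometric stress vs pCa.

    Stress is computed on the 9-point grid pCa = 5 .. 7 in steps of 0.25
    (pCa = 6 - log10(Cai/uM)) and fitted with
    Sa = Samax / (1 + 10^(h*(pCa - pCa50))).
    """
    import lmfit

    pca = np.arange(5.0, 7.0 + 1e-9, 0.25)
    cai = 10.0 ** (6.0 - pca)
    sa = np.array([steady_state_active_stress(params, c) for c in cai])
    if sa.max() <= 1e-12:
        raise RuntimeError("active stress is identically zero; Hill fit undefined")
    dec = np.diff(sa[np.argsort(-pca)])  # stress along increasing Ca
    if np.any(dec < -1e-9 * sa.max()):
        raise RuntimeError("stress-pCa data non-monotone beyond tolerance")

    model = lmfit.Model(
        lambda x, samax, pca50, h: samax / (1.0 + 10.0 ** (h * (x - pca50)))
    )
    fit = model.fit(
        sa,
        x=pca,
        samax=lmfit.Parameter("samax", value=float(sa.max()), min=1e-9),
        pca50=lmfit.Parameter("pca50", value=6.0, min=3.0, max=9.0),
        h=lmfit.Parameter("h", value=2.0, min=0.1, max=20.0),
    )
    pca50 = float(fit.params["pca50"].value)
    return CaSensitivity(
        pca50=pca50,
        ca50_um=float(10.0 ** (6.0 - pca50)),
        hill=float(fit.params["h"].value),
        samax=float(fit.params["samax"].value),
    )


# -- IC50 of percentage-shortening reduction ---------------------------------

@dataclass(frozen=True)
class IC50Short:
    """Half-maximal Short-reduction concentration; censored if no effect
    reached -25 % (reported as > top concentration)."""

    ic50_um: float
    hill: float
    censored: bool
    top_concentration_um: float

    def __str__(self) -> str:
        if self.censored:
            return f"- (> {self.top_concentration_um:g} uM)"
        return f"{self.ic50_um:.4g} uM"


def ic50_short(
    effects_pct: Sequence[float], concentrations_um: Sequence[float]
) -> IC50Short:
    """Hill fit of Short drug effects with the floor fixed at -100 %.

    Fits E(C) = -100 * C^h / (C^h + IC50^h) (complete-inhibition
    assumption).  If no effect reaches -25 %, the estimate is censored at
    the top concentration.
    """
    import lmfit

    eff = np.asarray(effects_pct, dtype=float)
    concs = np.asarray(concentrations_um, dtype=float)
    if eff.shape != concs.shape or eff.size < 3:
        raise ValueError("need >= 3 matched (concentration, effect) pairs")
    top = float(concs.max())
    if not np.any(eff <= -25.0):
        return IC50Short(math.nan, math.nan, True, top)

    def hill_inhib(x, log_ic50, h):
        ic50 = 10.0 ** log_ic50
        return -100.0 * x ** h / (x ** h + ic50 ** h)

    model = lmfit.Model(hill_inhib)
    fit = model.fit(
        eff,
        x=concs,
        log_ic50=lmfit.Parameter("log_ic50", value=float(np.log10(top)), min=-8, max=8),
        h=lmfit.Parameter("h", value=1.0, min=0.2, max=6.0),
    )
    return IC50Short(
        ic50_um=float(10.0 ** fit.params["log_ic50"].value),
        hill=float(fit.params["h"].value),
        censored=False,
        top_concentration_um=top,
    )
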