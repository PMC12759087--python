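"""Parameter sets, stimulus protocols and drug scaling for the cell models.

The rat and human left-ventricular cardiomyocyte models used here are
reduced-but-mechanistic reference implementations behind a fixed contract:
a minimal action-potential layer (the species' drug-scalable sarcolemmal
currents with Hodgkin-Huxley gating) drives a compartmental Ca2+ subsystem
(L-type influx, RyR2 release with a recovery gate, SERCA2 uptake, NCX1 /
plasma-membrane pump / background extrusion, SR leak in rat, a dyadic
subspace in human) coupled to a Land-type contraction component whose
active/passive stress balance yields the sarcomere-length transient.

Each protein of Table-1 drug pharmacology maps to exactly one maximal
conductance or rate; a pharmacological scaling factor multiplies that
parameter (``I_drug = I_base * s``).  Proteins absent from a species cannot
be scaled in that species.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "TARGET_PARAM",
    "StimulusProtocol",
    "CellModelParams",
    "rat_params",
    "human_params",
    "apply_scaling",
    "calmodulin_buffer_factor",
    "catrpn_dynamics",
]

#: Flat kernel parameter layout (absent entries are zero for a species).
PARAM_NAMES = (
    "g_NaL",      # 0  late Na+ conductance (Nav1.5-late), mS/uF
    "g_CaL",      # 1  L-type Ca2+ conductance (Cav1.2)
    "g_to",       # 2  transient outward K+ (Kv4.3)
    "g_K1",       # 3  inward rectifier K+ (Kir2.1)
    "g_RyR",      # 4  SR release rate (RyR2), 1/ms
    "V_SERCA",    # 5  max SR uptake (SERCA2), uM/ms
    "g_NCX",      # 6  Na+/Ca2+ exchanger scale (NCX1)
    "g_NaK",      # 7  Na+/K+ pump scale (NKA)
    "g_Na",       # 8  peak Na+ conductance (Nav1.5-peak, human only)
    "g_Kr",       # 9  rapid delayed rectifier (hERG, human only)
    "g_Ks",       # 10 slow delayed rectifier (KvLQT1/minK, human only)
    "g_pCa",      # 11 plasma-membrane Ca2+ pump
    "g_Cab",      # 12 background Ca2+ conductance
    "k_leak",     # 13 SR leak rate (rat), 1/ms, gradient driven
    "K_up",       # 14 SERCA Km, uM
    "tau_w",      # 15 RyR recovery time constant, ms
    "K_w",        # 16 RyR inactivation Km, uM
    "conv_Ca",    # 17 current-to-flux factor A/(2*F*v_myo), uM/ms per uA/uF
    "vr_sr",      # 18 v_myo / v_sr
    "CMDN_tot",   # 19 calmodulin buffer, uM
    "K_CMDN",     # 20 calmodulin Kd, uM
    "CSQN_tot",   # 21 SR calsequestrin buffer, uM
    "K_CSQN",     # 22 calsequestrin Kd, uM
    "kTRPN",      # 23 troponin C binding rate, 1/ms
    "nTRPN",      # 24 troponin Hill coefficient
    "Ca50ref",    # 25 troponin Ca sensitivity at lambda = 1, uM
    "CaTRPN_max", # 26 max Ca2+ bindable to troponin C, uM
    "k_xb",       # 27 crossbridge turnover rate, 1/ms
    "n_xb",       # 28 permissivity exponent
    "k_p",        # 29 passive restoring stiffness (normalised)
    "c_a",        # 30 active tension vs passive stiffness scale
    "eta",        # 31 viscous relaxation constant, ms
    "beta0",      # 32 length dependence of active tension
    "beta1",      # 33 length dependence of Ca50
    "SL0",        # 34 resting sarcomere length, um
    "Nai",        # 35 intracellular [Na+] (clamped), mM
    "Nao",        # 36 extracellular [Na+], mM
    "Cao",        # 37 extracellular [Ca2+], mM
    "Ko",         # 38 extracellular [K+], mM
    "Ki",         # 39 intracellular [K+] (clamped), mM
    "k_diff",     # 40 subspace-to-myoplasm transfer rate (human), 1/ms
    "vr_ss",      # 41 v_myo / v_ss (human)
    "K_fCa",      # 42 Ca-dependent LCC inactivation Km, uM
    "E_CaL",      # 43 effective LCC reversal potential, mV
    "tau_d",      # 44 LCC activation tau, ms
    "tau_f",      # 45 LCC voltage inactivation tau, ms
    "tau_r",      # 46 Ito activation tau, ms
    "tau_s",      # 47 Ito inactivation tau, ms
    "tau_hNaL",   # 48 late Na inactivation tau, ms
    "tau_m",      # 49 fast Na activation tau, ms (human)
    "tau_h",      # 50 fast Na inactivation tau, ms (human)
    "tau_xr",     # 51 IKr activation tau, ms (human)
    "tau_xs",     # 52 IKs activation tau, ms (human)
    "g_NaF",      # 53 non-druggable fast Na+ conductance (rat upstroke)
)

P_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

STATE_NAMES = (
    "V",        # 0 membrane potential, mV
    "Cai",      # 1 free intracellular [Ca2+], uM
    "CaSR",     # 2 SR [Ca2+], uM
    "Cass",     # 3 dyadic subspace [Ca2+], uM (human)
    "w",        # 4 RyR recovery gate
    "d",        # 5 LCC activation
    "f",        # 6 LCC voltage inactivation
    "r",        # 7 Ito activation
    "s",        # 8 Ito inactivation
    "hNaL",     # 9 late Na inactivation
    "m",        # 10 fast Na activation (human)
    "h",        # 11 fast Na inactivation (human)
    "xr",       # 12 IKr activation (human)
    "xs",       # 13 IKs activation (human)
    "CaTRPN",   # 14 troponin C occupancy fraction
    "XB",       # 15 crossbridge activation
    "lam",      # 16 sarcomere stretch SL/SL0
)

S_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Drug target protein -> scaled parameter.
TARGET_PARAM = {
    "Nav1.5-late": "g_NaL",
    "Cav1.2": "g_CaL",
    "Kv4.3": "g_to",
    "Kir2.1": "g_K1",
    "RyR2": "g_RyR",
    "SERCA2": "V_SERCA",
    "NCX1": "g_NCX",
    "NKA": "g_NaK",
    "Nav1.5-peak": "g_Na",
    "hERG": "g_Kr",
    "KvLQT1/minK": "g_Ks",
}

_HUMAN_ONLY_PARAMS = (
    "g_Na", "g_Kr", "g_Ks", "k_diff", "vr_ss", "tau_xr", "tau_xs",
)
_RAT_ONLY_PARAMS = ("g_NaF",)

#: Conductance/rate parameters that must be strictly positive when present.
_POSITIVE = (
    "g_CaL", "g_to", "g_K1", "g_RyR", "V_SERCA", "g_NCX", "g_NaK",
    "K_up", "tau_w", "K_w", "conv_Ca", "vr_sr", "K_CMDN", "K_CSQN",
    "kTRPN", "nTRPN", "Ca50ref", "CaTRPN_max", "k_xb", "n_xb", "k_p", "c_a",
    "eta", "Nai", "Nao", "Cao", "Ko", "Ki", "K_fCa",
    "tau_d", "tau_f", "tau_r", "tau_s", "tau_hNaL", "tau_m", "tau_h",
)

#: Default stimulus time integral, uA*ms/cm^2.
STIM_INTEGRAL = 50.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Monophasic pacing protocol.

    The stimulus time integral (amplitude x duration) is preserved when the
    duration changes: the amplitude is rescaled to keep the configured
    integral (default 50 uA*ms/cm^2).
    """

    frequency: float = 1.0     # Hz
    duration: float = 1.0      # ms
    n_beats: int = 100
    dt_solver: float = 0.01    # ms
    dt_output: float = 1.0     # ms
    integral: float = STIM_INTEGRAL  # uA*ms/cm^2
    shape: str = "monophasic"

    def __post_init__(self) -> None:
        if self.shape != "monophasic":
            raise ValueError("only monophasic stimuli are supported")
        if self.frequency <= 0 or self.duration <= 0:
            raise ValueError("frequency and duration must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.dt_solver > self.dt_output:
            raise ValueError("dt_solver must be <= dt_output")

    @property
    def amplitude(self) -> float:
        """Stimulus amplitude in uA/cm^2 preserving the time integral."""
        return self.integral / self.duration

    @property
    def period(self) -> float:
        return 1000.0 / self.frequency

    def with_(self, **kw) -> "StimulusProtocol":
        return replace(self, **kw)


@dataclass(frozen=True)
class CellModelParams:
    """Species-specific parameter set (names as in PARAM_NAMES).

    Parameters a species does not possess (Table-1 blanks and their gating
    constants) are not present in ``values``.
    """

    species: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.species not in ("rat", "human"):
            raise ValueError("species must be 'rat' or 'human'")
        vals = dict(self.values)
        absent = _HUMAN_ONLY_PARAMS if self.species == "rat" else _RAT_ONLY_PARAMS
        for name in vals:
            if name not in P_INDEX:
                raise ValueError(f"unknown parameter {name!r}")
            if name in absent:
                raise ValueError(f"parameter {name!r} is absent in {self.species}")
        for name in _POSITIVE:
            if name in vals and vals[name] <= 0.0:
                raise ValueError(f"parameter {name!r} must be > 0")
        sl0 = vals.get("SL0", 1.8)
        if not (1.4 <= sl0 <= 2.2):
            raise ValueError("SL0 must lie within [1.4, 2.2] um")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    @property
    def targets(self) -> tuple[str, ...]:
        """Drug targets present in this species."""
        return tuple(
            t for t, p in TARGET_PARAM.items() if p in self.values
        )

    def to_array(self) -> np.ndarray:
        arr = np.zeros(len(PARAM_NAMES))
        for name, v in self.values.items():
            arr[P_INDEX[name]] = v
        return arr

    def with_values(self, **kw: float) -> "CellModelParams":
        vals = dict(self.values)
        vals.update(kw)
        return CellModelParams(self.species, vals)

    def digest(self) -> str:
        """Stable content hash (used as a baseline-cache key)."""
        h = hashlib.sha1()
        h.update(self.species.encode())
        h.update(self.to_array().tobytes())
        return h.hexdigest()

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"species": self.species, "values": dict(self.values)}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "CellModelParams":
        import json

        obj = json.loads(text)
        return cls(obj["species"], {k: float(v) for k, v in obj["values"].items()})


def apply_scaling(
    params: CellModelParams, scaling: Mapping[str, float]
) -> CellModelParams:
    """Multiply each targeted maximal conductance/rate by its scaling factor.

    Raises if a scaled protein is absent from the species (e.g. hERG in
    rat) or if a factor lies outside (0, 1].
    """
    if not scaling:
        return params
    updates: dict[str, float] = {}
    for protein, s in scaling.items():
        if protein not in TARGET_PARAM:
            raise ValueError(f"unknown drug target {protein!r}")
        pname = TARGET_PARAM[protein]
        if pname not in params.values:
            raise ValueError(
                f"target {protein!r} is not present in the {params.species} model"
            )
        if not (0.0 < s <= 1.0):
            raise ValueError(f"scaling factor for {protein} must be in (0, 1]")
        updates[pname] = params[pname] * float(s)
    return params.with_values(**updates)


def calmodulin_buffer_factor(cai: float, cmdn_tot: float, k_cmdn: float) -> float:
    """Rapid-buffering factor beta(Cai) = 1/(1 + CMDN*K/(Cai+K)^2).

    ``beta`` multiplies the net flux in dCai/dt; any consistent
    concentration unit may be used for the three arguments.
    """
    if k_cmdn <= 0.0:
        raise ValueError("K_CMDN must be > 0")
    if cmdn_tot < 0.0:
        raise ValueError("CMDN_tot must be >= 0")
    if cai <= 0.0:
        raise ValueError("Cai must be > 0")
    return 1.0 / (1.0 + cmdn_tot * k_cmdn / (cai + k_cmdn) ** 2)


def catrpn_dynamics(
    cai: float,
    catrpn: float,
    k_trpn: float,
    ca50: float,
    n_trpn: float,
    catrpn_max: float,
) -> tuple[float, float]:
    """Troponin C binding kinetics.

    Returns ``(dCaTRPN/dt, d[Ca-TRPN]/dt)``: the rate of the bound fraction
    and, multiplied by the maximal bindable concentration, the bound-Ca rate
    that is subtracted from dCai/dt.
    """
    if not (0.0 <= catrpn <= 1.0):
        raise ValueError("CaTRPN fraction must lie in [0, 1]")
    if min(k_trpn, ca50, n_trpn, catrpn_max) <= 0.0:
        raise ValueError("troponin parameters must be > 0")
    if cai < 0.0:
        raise ValueError("Cai must be >= 0")
    rate = k_trpn * ((cai / ca50) ** n_trpn * (1.0 - catrpn) - catrpn)
    return rate, catrpn_max * rate


# -- reference parameter sets -------------------------------------------------
# Repo-chosen values, calibrated so baseline biomarkers fall inside the
# experimental ranges and the pacing-frequency relationship signs hold
# (negative Short/CaAmp staircase in rat, positive in human).

_RAT_VALUES: dict[str, float] = {
    "g_NaL": 0.002,
    "g_CaL": 0.45,
    "g_to": 5.6,
    "g_K1": 0.15,
    "g_RyR": 0.018,
    "V_SERCA": 0.28,
    "g_NCX": 1200.0,
    "g_NaK": 1.2,
    "g_pCa": 0.07,
    "g_Cab": 0.0012,
    "k_leak": 5.0e-5,
    "K_up": 0.35,
    "tau_w": 900.0,
    "K_w": 0.35,
    "conv_Ca": 0.012,
    "vr_sr": 18.0,
    "CMDN_tot": 50.0,
    "K_CMDN": 2.38,
    "CSQN_tot": 8000.0,
    "K_CSQN": 800.0,
    "kTRPN": 0.06,
    "nTRPN": 2.0,
    "Ca50ref": 1.2,
    "CaTRPN_max": 70.0,
    "k_xb": 0.06,
    "n_xb": 2.0,
    "k_p": 1.0,
    "c_a": 0.7,
    "eta": 10.0,
    "beta0": 2.3,
    "beta1": -2.4,
    "SL0": 1.878,
    "Nai": 12.0,
    "Nao": 140.0,
    "Cao": 1.8,
    "Ko": 5.4,
    "Ki": 140.0,
    "K_fCa": 1.5,
    "E_CaL": 60.0,
    "tau_d": 5.0,
    "tau_f": 10.0,
    "tau_r": 1.5,
    "tau_s": 25.0,
    "tau_hNaL": 40.0,
    "tau_m": 0.2,
    "tau_h": 4.0,
    "g_NaF": 12.0,
}

_HUMAN_VALUES: dict[str, float] = {
    "g_NaL": 0.02,
    "g_CaL": 0.15,
    "g_to": 0.08,
    "g_K1": 0.25,
    "g_RyR": 0.003,
    "V_SERCA": 0.55,
    "g_NCX": 2500.0,
    "g_NaK": 1.2,
    "g_Na": 8.0,
    "g_Kr": 0.03,
    "g_Ks": 0.02,
    "g_pCa": 0.03,
    "g_Cab": 0.0012,
    "k_leak": 2.0e-4,
    "K_up": 0.4,
    "tau_w": 35.0,
    "K_w": 0.6,
    "conv_Ca": 0.008,
    "vr_sr": 20.0,
    "CMDN_tot": 50.0,
    "K_CMDN": 2.38,
    "CSQN_tot": 8000.0,
    "K_CSQN": 800.0,
    "kTRPN": 0.025,
    "nTRPN": 2.0,
    "Ca50ref": 0.4,
    "CaTRPN_max": 70.0,
    "k_xb": 0.02,
    "n_xb": 2.0,
    "k_p": 1.0,
    "c_a": 0.25,
    "eta": 30.0,
    "beta0": 2.3,
    "beta1": -2.4,
    "SL0": 1.790,
    "Nai": 8.0,
    "Nao": 140.0,
    "Cao": 1.8,
    "Ko": 5.4,
    "Ki": 140.0,
    "k_diff": 0.08,
    "vr_ss": 40.0,
    "K_fCa": 15.0,
    "E_CaL": 60.0,
    "tau_d": 3.0,
    "tau_f": 150.0,
    "tau_r": 3.0,
    "tau_s": 60.0,
    "tau_hNaL": 200.0,
    "tau_m": 0.3,
    "tau_h": 6.0,
    "tau_xr": 120.0,
    "tau_xs": 400.0,
}


def rat_params(**overrides: float) -> CellModelParams:
    """Reference rat left-ventricular cardiomyocyte parameter set."""
    vals = dict(_RAT_VALUES)
    vals.update(overrides)
    return CellModelParams("rat", vals)


def human_params(**overrides: float) -> CellModelParams:
    """Reference human left-ventricular cardiomyocyte parameter set."""
    vals = dict(_HUMAN_VALUES)
    vals.update(overrides)
    return CellModelParams("human", vals)
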