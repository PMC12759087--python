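"""Fixed-step integration kernel for the coupled electromechanics models.

Gating variables are advanced with the Rush-Larsen scheme (exact
exponential update of dx/dt = (x_inf - x)/tau); all other states use the
forward Euler method.  The default solver step is 0.01 ms with output
decimated to 1 ms.  The kernel is shared by both species: a flag selects
the human-only currents (IKr, IKs) and the dyadic subspace.

Voltage-dependent gate steady states, the NCX exponentials and the NaK
voltage factor are tabulated on a 0.05 mV grid over [-120, 80] mV and
linearly interpolated, which removes almost all per-step transcendentals.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

RTF = 26.712  # RT/F at 310 K, mV

#: status codes returned by the kernel
OK = 0
NONFINITE = 1
NEGATIVE_CA = 2

# voltage table layout
V_MIN = -120.0
V_MAX = 80.0
V_STEP = 0.05
N_V = int(round((V_MAX - V_MIN) / V_STEP)) + 1

_F_MNAL, _F_D, _F_F, _F_R, _F_S, _F_HNAL, _F_M, _F_H, _F_XR, _F_XS = range(10)
_F_K1, _F_KRR, _F_E1, _F_E2, _F_NAK = range(10, 15)
N_FUN = 15


def _sigmoid(v: np.ndarray, mid: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(v - mid) / slope))


def build_voltage_tables() -> np.ndarray:
    """Tabulated voltage-dependent factors (gate steady states etc.)."""
    v = V_MIN + V_STEP * np.arange(N_V)
    tab = np.empty((N_FUN, N_V))
    tab[_F_MNAL] = _sigmoid(v, -42.0, 6.0)
    tab[_F_D] = _sigmoid(v, -15.0, 6.0)
    tab[_F_F] = _sigmoid(v, -38.0, -5.5)
    tab[_F_R] = _sigmoid(v, -10.0, 8.0)
    # Ito inactivation retains a non-inactivating fraction (steady-state
    # outward K+ component of the rodent AP)
    tab[_F_S] = 0.2 + 0.8 * _sigmoid(v, -40.0, -5.0)
    tab[_F_HNAL] = _sigmoid(v, -70.0, -6.0)
    tab[_F_M] = _sigmoid(v, -40.0, 6.0)
    tab[_F_H] = _sigmoid(v, -70.0, -6.0)
    tab[_F_XR] = _sigmoid(v, -15.0, 7.0)
    tab[_F_XS] = _sigmoid(v, 0.0, 12.0)
    tab[_F_K1] = 1.0 / (1.0 + np.exp((v + 55.0) / 14.0))
    tab[_F_KRR] = 1.0 / (1.0 + np.exp((v + 35.0) / 25.0))
    tab[_F_E1] = np.exp(0.35 * v / RTF)
    tab[_F_E2] = np.exp(-0.65 * v / RTF)
    tab[_F_NAK] = 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * v / RTF) + 0.0365 * np.exp(-v / RTF)
    )
    return tab


VOLTAGE_TABLES = build_voltage_tables()


@njit(cache=True, fastmath=True, inline="always")
def _lut(tab, row, pos, frac):
    a = tab[row, pos]
    return a + frac * (tab[row, pos + 1] - a)


@njit(cache=True, fastmath=True)
def integrate(
    is_human,
    P,
    tab,
    y,
    n_beats,
    period,
    stim_amp,
    stim_dur,
    dt,
    out_stride,
    out_v,
    out_cai,
    out_sl,
):
    """Pace the model for ``n_beats`` periods, writing decimated output.

    ``y`` (length 17) is updated in place to the final state.  Returns
    (status, t_fail): OK, or NONFINITE/NEGATIVE_CA with the failure time.
    """
    # unpack parameters (indices follow PARAM_NAMES)
    g_NaL = P[0]; g_CaL = P[1]; g_to = P[2]; g_K1 = P[3]
    g_RyR = P[4]; V_SERCA = P[5]; g_NCX = P[6]; g_NaK = P[7]
    g_Na = P[8]; g_Kr = P[9]; g_Ks = P[10]
    g_pCa = P[11]; g_Cab = P[12]; k_leak = P[13]
    K_up = P[14]; tau_w = P[15]; K_w = P[16]
    conv = P[17]; vr_sr = P[18]
    CMDN = P[19]; K_CMDN = P[20]; CSQN = P[21]; K_CSQN = P[22]
    kTRPN = P[23]; nTRPN = P[24]; Ca50ref = P[25]; CaTRPN_max = P[26]
    k_xb = P[27]; n_xb = P[28]; k_p = P[29]; c_a = P[30]; eta = P[31]
    beta0 = P[32]; beta1 = P[33]; SL0 = P[34]
    Nai = P[35]; Nao = P[36]; Cao = P[37]; Ko = P[38]; Ki = P[39]
    k_diff = P[40]; vr_ss = P[41]; K_fCa = P[42]; E_CaL = P[43]
    g_NaF = P[53]

    E_K = RTF * math.log(Ko / Ki)
    E_Na = RTF * math.log(Nao / Nai)
    na3 = Nai * Nai * Nai
    nao3 = Nao * Nao * Nao
    ncx_den0 = (87.5 ** 3 + nao3) * (1.38 + Cao)
    nak_na = (Nai / (Nai + 10.0)) ** 3
    gNa_tot = g_Na + g_NaF
    Kw4 = K_w ** 4
    K_up2 = K_up * K_up
    inv_Kf2 = 1.0 / (K_fCa * K_fCa)
    trpn_sq = nTRPN == 2.0
    xb_sq = n_xb == 2.0
    inv_vstep = 1.0 / V_STEP

    # Rush-Larsen decay factors for constant-tau gates
    rl_d = 1.0 - math.exp(-dt / P[44])
    rl_f = 1.0 - math.exp(-dt / P[45])
    rl_r = 1.0 - math.exp(-dt / P[46])
    rl_s = 1.0 - math.exp(-dt / P[47])
    rl_hNaL = 1.0 - math.exp(-dt / P[48])
    rl_m = 1.0 - math.exp(-dt / P[49])
    rl_h = 1.0 - math.exp(-dt / P[50])
    rl_xr = 1.0 - math.exp(-dt / P[51]) if is_human else 0.0
    rl_xs = 1.0 - math.exp(-dt / P[52]) if is_human else 0.0
    rl_w = 1.0 - math.exp(-dt / tau_w)

    V = y[0]; Cai = y[1]; CaSR = y[2]; Cass = y[3]
    w = y[4]; d = y[5]; f = y[6]; r = y[7]; s = y[8]; hNaL = y[9]
    m = y[10]; h = y[11]; xr = y[12]; xs = y[13]
    CaTRPN = y[14]; XB = y[15]; lam = y[16]

    n_steps = int(round(period * n_beats / dt))
    steps_per_period = int(round(period / dt))
    stim_steps = int(round(stim_dur / dt))
    k = 0
    for i in range(n_steps):
        # voltage-table position
        vq = V
        if vq < V_MIN:
            vq = V_MIN
        elif vq > V_MAX - V_STEP:
            vq = V_MAX - V_STEP
        x = (vq - V_MIN) * inv_vstep
        pos = int(x)
        frac = x - pos

        Cat = Cass if is_human else Cai  # trigger Ca for LCC inact. and RyR
        cai_mM = Cai * 1.0e-3

        # --- currents -------------------------------------------------
        i_Na = gNa_tot * m * m * m * h * (V - E_Na)
        i_NaL = g_NaL * _lut(tab, _F_MNAL, pos, frac) * hNaL * (V - E_Na)
        f_Ca = 1.0 / (1.0 + Cat * Cat * inv_Kf2)
        i_CaL = g_CaL * d * f * f_Ca * (V - E_CaL)
        i_to = g_to * r * s * (V - E_K)
        i_K1 = g_K1 * _lut(tab, _F_K1, pos, frac) * (V - E_K)
        e1 = _lut(tab, _F_E1, pos, frac)
        e2 = _lut(tab, _F_E2, pos, frac)
        i_NCX = g_NCX * (e1 * na3 * Cao - e2 * nao3 * cai_mM) / (
            ncx_den0 * (1.0 + 0.1 * e2)
        )
        i_NaK = g_NaK * nak_na * _lut(tab, _F_NAK, pos, frac)
        i_pCa = g_pCa * Cai / (Cai + 0.5)
        E_Ca = 0.5 * RTF * math.log(Cao / cai_mM)
        i_Cab = g_Cab * (V - E_Ca)

        i_ion = i_Na + i_NaL + i_CaL + i_to + i_K1 + i_NCX + i_NaK + i_pCa + i_Cab
        if is_human:
            i_Kr = g_Kr * xr * _lut(tab, _F_KRR, pos, frac) * (V - E_K)
            i_Ks = g_Ks * xs * xs * (V - E_K)
            i_ion += i_Kr + i_Ks

        i_stim = -stim_amp if (i % steps_per_period) < stim_steps else 0.0

        # --- Ca fluxes ------------------------------------------------
        po = d * w  # graded, trigger-gated release (local-control approx.)
        j_up = V_SERCA * Cai * Cai / (Cai * Cai + K_up2)
        ca50 = Ca50ref * (1.0 + beta1 * (lam - 1.0))
        if ca50 < 0.05 * Ca50ref:
            ca50 = 0.05 * Ca50ref
        rho = Cai / ca50
        rho_n = rho * rho if trpn_sq else rho ** nTRPN
        dCaTRPN = kTRPN * (rho_n * (1.0 - CaTRPN) - CaTRPN)
        j_trpn = CaTRPN_max * dCaTRPN

        beta_i = 1.0 / (1.0 + CMDN * K_CMDN / ((Cai + K_CMDN) * (Cai + K_CMDN)))
        beta_sr = 1.0 / (
            1.0 + CSQN * K_CSQN / ((CaSR + K_CSQN) * (CaSR + K_CSQN))
        )

        if is_human:
            j_rel = g_RyR * po * (CaSR - Cass)
            j_leak = k_leak * (CaSR - Cai)
            j_diff = k_diff * (Cass - Cai)
            dCass = vr_ss * (conv * (-i_CaL) + j_rel - j_diff)
            dCai = beta_i * (
                conv * (2.0 * i_NCX - i_pCa - i_Cab)
                + j_diff - j_up + j_leak - j_trpn
            )
            dCaSR = beta_sr * vr_sr * (j_up - j_rel - j_leak)
        else:
            j_rel = g_RyR * po * (CaSR - Cai)
            j_leak = k_leak * (CaSR - Cai)
            dCass = 0.0
            dCai = beta_i * (
                conv * (2.0 * i_NCX - i_pCa - i_Cab - i_CaL)
                + j_rel - j_up + j_leak - j_trpn
            )
            dCaSR = beta_sr * vr_sr * (j_up - j_rel - j_leak)

        # --- contraction ---------------------------------------------
        perm = CaTRPN * CaTRPN if xb_sq else CaTRPN ** n_xb
        dXB = k_xb * (perm - XB)
        hl = 1.0 + beta0 * (lam - 1.0)
        if hl < 0.0:
            hl = 0.0
        Ta = XB * hl
        dlam = (k_p * (1.0 - lam) - c_a * Ta) / eta

        # --- advance (forward Euler for non-gates) -------------------
        V += dt * (-(i_ion) - i_stim)
        Cai += dt * dCai
        CaSR += dt * dCaSR
        if is_human:
            Cass += dt * dCass
        CaTRPN += dt * dCaTRPN
        if CaTRPN < 0.0:
            CaTRPN = 0.0
        elif CaTRPN > 1.0:
            CaTRPN = 1.0
        XB += dt * dXB
        if XB < 0.0:
            XB = 0.0
        elif XB > 1.0:
            XB = 1.0
        lam += dt * dlam
        if lam < 0.4:
            lam = 0.4

        # --- Rush-Larsen gate updates --------------------------------
        ct2 = Cat * Cat
        w += (Kw4 / (Kw4 + ct2 * ct2) - w) * rl_w
        d += (_lut(tab, _F_D, pos, frac) - d) * rl_d
        f += (_lut(tab, _F_F, pos, frac) - f) * rl_f
        r += (_lut(tab, _F_R, pos, frac) - r) * rl_r
        s += (_lut(tab, _F_S, pos, frac) - s) * rl_s
        hNaL += (_lut(tab, _F_HNAL, pos, frac) - hNaL) * rl_hNaL
        m += (_lut(tab, _F_M, pos, frac) - m) * rl_m
        h += (_lut(tab, _F_H, pos, frac) - h) * rl_h
        if is_human:
            xr += (_lut(tab, _F_XR, pos, frac) - xr) * rl_xr
            xs += (_lut(tab, _F_XS, pos, frac) - xs) * rl_xs

        # --- output & validity ---------------------------------------
        if i % out_stride == 0:
            out_v[k] = V
            out_cai[k] = Cai
            out_sl[k] = lam * SL0
            k += 1
        if not (V == V) or not (Cai == Cai):
            return NONFINITE, i * dt
        if Cai <= 0.0 or CaSR <= 0.0:
            return NEGATIVE_CA, i * dt

    y[0] = V; y[1] = Cai; y[2] = CaSR; y[3] = Cass
    y[4] = w; y[5] = d; y[6] = f; y[7] = r; y[8] = s; y[9] = hNaL
    y[10] = m; y[11] = h; y[12] = xr; y[13] = xs
    y[14] = CaTRPN; y[15] = XB; y[16] = lam
    return OK, 0.0


def initial_state(is_human: bool) -> np.ndarray:
    """Resting initial conditions (full relaxation, diastolic Ca)."""
    y = np.zeros(17)
    y[0] = -80.0           # V
    y[1] = 0.1             # Cai uM
    y[2] = 700.0           # CaSR uM
    y[3] = 0.1             # Cass
    y[4] = 1.0             # w
    y[5] = 0.0             # d
    y[6] = 1.0             # f
    y[7] = 0.0             # r
    y[8] = 1.0             # s
    y[9] = 0.6             # hNaL
    y[10] = 0.0            # m
    y[11] = 0.7            # h
    y[12] = 0.0            # xr
    y[13] = 0.0            # xs
    y[14] = 0.01           # CaTRPN
    y[15] = 0.0            # XB
    y[16] = 1.0            # lam
    return y
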