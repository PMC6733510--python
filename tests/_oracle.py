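"""Second, independent transcription of the model equations.

This module re-codes the published equation set from scratch in plain scalar
numpy, organized current-by-current with named intermediates, and is used
only to cross-check the packaged (numba) right-hand side at random states.
It deliberately shares no code with ``hipsc_ap._kernels``.
"""

from __future__ import annotations

import numpy as np

exp = np.exp
log = np.log
sqrt = np.sqrt


def _if_gate(v_mV, formulation):
    if formulation == "paci":
        x_inf = 1 / (1 + exp((v_mV + 77.85) / 5))
        tau = 1.9 / (1 + exp((v_mV + 15) / 10))
    elif formulation == "severi2012":
        x_inf = 1 / (1 + exp((v_mV + 52.5) / 9))
        tau = 0.7166529 / (0.0708 * exp(-(v_mV + 5) / 20.2791)
                           + 10.6 * exp(v_mV / 18))
    elif formulation == "fabbri2017":
        if v_mV < -80:
            x_inf = min(1.0, 0.01329 + 0.99921 / (1 + exp((v_mV + 97.134) / 8.1752)))
        else:
            x_inf = 0.0002501 * exp(-v_mV / 12.861)
        a = 0.36 * (v_mV + 148.8) / (exp(0.066 * (v_mV + 148.8)) - 1)
        b = 0.1 * (v_mV + 87.3) / (1 - exp(-0.2 * (v_mV + 87.3)))
        tau = max(1 / (a + b) - 0.054, 1e-3)
    elif formulation == "koivumaki2018":
        x_inf = 1 / (1 + exp((v_mV + 96.9) / 8.8))
        tau = 0.1 + 1.3 * exp(-(((v_mV + 90) / 30) ** 2))
    else:
        raise ValueError(formulation)
    return x_inf, tau


def derivatives(state: dict, params: dict, variant: str,
                if_formulation: str = "paci") -> dict:
    """d(state)/dt as a dict of named components (SI units)."""
    F = params["F"]
    R = params["R"]
    T = params["T"]
    V = state["Vm"]
    v = V * 1000.0
    Nai = state["Nai"]
    Cai = state["Cai"]
    CaSR = state["Ca_SR"]
    Nao, Ko, Cao, Ki = params["Nao"], params["Ko"], params["Cao"], params["Ki"]

    E_Na = R * T / F * log(Nao / Nai)
    E_K = R * T / F * log(Ko / Ki)
    E_Ks = R * T / F * log((Ko + params["PkNa"] * Nao) / (Ki + params["PkNa"] * Nai))
    E_Ca = 0.5 * R * T / F * log(Cao / Cai)

    # --- fast sodium ------------------------------------------------------
    INa = params["gNa"] * state["m"] ** 3 * state["h"] * state["j"] * (V - E_Na)
    m_inf = (1 + exp((-v - 34.1) / 5.9)) ** (-1 / 3)
    tau_m = (1 / (1 + exp((-v - 60) / 5))) \
        * (0.1 / (1 + exp((v + 35) / 5)) + 0.1 / (1 + exp((v - 50) / 200))) / 1000
    h_inf = 1 / sqrt(1 + exp((v + 72.1) / 5.7))
    if v < -40:
        a_h = 0.057 * exp(-(v + 80) / 6.8)
        b_h = 2.7 * exp(0.079 * v) + 3.1e5 * exp(0.3485 * v)
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1 + exp(-(v + 10.66) / 11.1)))
    tau_h = 1.5 / (a_h + b_h) / 1000
    j_inf = h_inf
    if v < -40:
        a_j = (-25428 * exp(0.2444 * v) - 6.948e-6 * exp(-0.04391 * v)) \
            * (v + 37.78) / (1 + exp(0.311 * (v + 79.23)))
        b_j = 0.02424 * exp(-0.01052 * v) / (1 + exp(-0.1378 * (v + 40.14)))
    else:
        a_j = 0.0
        b_j = 0.6 * exp(0.057 * v) / (1 + exp(-0.1 * (v + 32)))
    tau_j = 7 / (a_j + b_j) / 1000

    # --- late sodium ------------------------------------------------------
    INaL = params["gNaL"] * state["mL"] ** 3 * state["hL"] * (V - E_Na)
    mL_inf = 1 / (1 + exp(-(v + 42.85) / 5.264))
    a_mL = 0.32 * (v + 47.13) / (1 - exp(-0.1 * (v + 47.13)))
    b_mL = 0.08 * exp(-v / 11)
    tau_mL = 1 / (a_mL + b_mL) / 1000
    hL_inf = 1 / (1 + exp((v + params["Vh_hLate"]) / 7.488))
    tau_hL = params["tau_hLate"]

    # --- L-type calcium ---------------------------------------------------
    zv = 2 * V * F / (R * T)
    ICaL = params["gCaL"] * 4 * V * F ** 2 / (R * T) \
        * (Cai * exp(zv) - 0.341 * Cao) / (exp(zv) - 1) \
        * state["d"] * state["f1"] * state["f2"] * state["fCa"]
    d_inf = 1 / (1 + exp(-(v + 9.1) / 7))
    tau_d = ((0.25 + 1.4 / (1 + exp((-v - 35) / 13)))
             * (1.4 / (1 + exp((v + 5) / 5)))
             + 1 / (1 + exp((-v + 50) / 20))) / 1000
    f1_inf = 1 / (1 + exp((v + 26) / 3))
    tau_f1 = (20 + 1102.5 * exp(-((((v + 27) ** 2) / 15) ** 2))
              + 200 / (1 + exp((13 - v) / 10))
              + 180 / (1 + exp((30 + v) / 10))) / 1000
    if f1_inf > state["f1"]:
        tau_f1 = tau_f1 * (1 + 1433 * (Cai - 50e-6))
    f2_inf = 0.33 + 0.67 / (1 + exp((v + 35) / 4))
    tau_f2 = (600 * exp(-((v + 25) ** 2) / 170)
              + 31 / (1 + exp((25 - v) / 10))
              + 16 / (1 + exp((30 + v) / 10))) / 1000
    fCa_inf = (1 / (1 + (Cai / 0.0006) ** 8)
               + 0.1 / (1 + exp((Cai - 0.0009) / 0.0001))
               + 0.3 / (1 + exp((Cai - 0.00075) / 0.0008))) / 1.3156
    if V > -0.06 and fCa_inf > state["fCa"]:
        k_fCa = 0.0
    else:
        k_fCa = 1.0

    # --- transient outward ------------------------------------------------
    Ito = params["gto"] * state["q"] * state["r"] * (V - E_K)
    q_inf = 1 / (1 + exp((v + 53) / 13))
    tau_q = (6.06 + 39.102 / (0.57 * exp(-0.08 * (v + 44))
                              + 0.065 * exp(0.1 * (v + 45.93)))) / 1000
    r_inf = 1 / (1 + exp(-(v - 22.3) / 18.75))
    tau_r = (2.75352 + 14.40516 / (1.037 * exp(0.09 * (v + 30.61))
                                   + 0.369 * exp(-0.12 * (v + 23.84)))) / 1000

    # --- rapid delayed rectifier -----------------------------------------
    IKr = params["gKr"] * sqrt(Ko / 5.4) * state["Xr1"] * state["Xr2"] * (V - E_K)
    V_half = 1000 * (-R * T / (F * params["Q"])
                     * log((1 + Cao / 2.6) ** 4
                           / (params["L0"] * (1 + Cao / 0.58) ** 4)) - 0.019)
    Xr1_inf = 1 / (1 + exp((V_half - v) / 4.9))
    tau_Xr1 = (450 / (1 + exp((-45 - v) / 10))) * (6 / (1 + exp((30 + v) / 11.5))) / 1000
    Xr2_inf = 1 / (1 + exp((v + 88) / 50))
    tau_Xr2 = (3 / (1 + exp((-60 - v) / 20))) * (1.12 / (1 + exp((-60 + v) / 20))) / 1000

    # --- slow delayed rectifier ------------------------------------------
    IKs = params["gKs"] * state["Xs"] ** 2 * (V - E_Ks) \
        * (1 + 0.6 / (1 + (3.8e-5 / Cai) ** 1.4))
    Xs_inf = 1 / (1 + exp((-v - 20) / 16))
    tau_Xs = (1100 / sqrt(1 + exp((-10 - v) / 6))) * (1 / (1 + exp((-60 + v) / 20))) / 1000

    # --- inward rectifier -------------------------------------------------
    dv = v - E_K * 1000
    a_K1 = 3.91 / (1 + exp(0.5942 * (dv - 200)))
    b_K1 = (-1.509 * exp(0.0002 * (dv + 100)) + exp(0.5886 * (dv - 10))) \
        / (1 + exp(0.4547 * dv))
    IK1 = params["gK1"] * sqrt(Ko / 5.4) * (a_K1 / (a_K1 + b_K1)) * (V - E_K)

    # --- funny current ----------------------------------------------------
    Xf = state["Xf"]
    gf = params["gf"]
    if if_formulation == "paci" and variant == "paci2017":
        If = gf * Xf * (V - params["E_f"])
        If_Na = 0.0
    elif if_formulation == "severi2012":
        kdep = Ko / (Ko + 45.0)
        If_Na = 0.5 * gf * Xf * kdep * (V - E_Na)
        If = If_Na + 0.5 * gf * Xf * kdep * (V - E_K)
    elif if_formulation == "fabbri2017":
        If_Na = 0.42 * gf * Xf * (V - E_Na)
        If = If_Na + 0.58 * gf * Xf * (V - E_K)
    else:  # native paci2018 split or koivumaki2018
        fna = params["fNaIf"]
        If_Na = fna * gf * Xf * (V - E_Na)
        If = If_Na + (1 - fna) * gf * Xf * (V - E_K)
    Xf_inf, tau_Xf = _if_gate(v, if_formulation)

    # --- pumps / exchangers / background ----------------------------------
    g_ncx = params["gamma"]
    INaCa = params["kNaCa"] * (
        exp(g_ncx * V * F / (R * T)) * Nai ** 3 * Cao
        - exp((g_ncx - 1) * V * F / (R * T)) * Nao ** 3 * Cai * params["alphaNaCa"]
    ) / (
        (params["KmNai"] ** 3 + Nao ** 3) * (params["KmCa"] + Cao)
        * (1 + params["Ksat"] * exp((g_ncx - 1) * V * F / (R * T)))
    )
    INaK = params["PNaK"] * Ko / (Ko + params["KmK"]) * Nai / (Nai + params["KmNa"]) \
        / (1 + 0.1245 * exp(-0.1 * V * F / (R * T))
           + 0.0353 * exp(-V * F / (R * T)))
    IpCa = params["gPCa"] * Cai / (Cai + params["KPCa"])
    IbNa = params["gbNa"] * (V - E_Na)
    IbCa = params["gbCa"] * (V - E_Ca)

    # --- SR fluxes --------------------------------------------------------
    Iup = params["VmaxUp"] / (1 + params["Kup"] ** 2 / Cai ** 2)
    Ileak = (CaSR - Cai) * params["V_leak"]
    d_g = 0.0
    d_RyRa = d_RyRo = d_RyRc = 0.0
    if variant == "paci2017":
        Irel = (params["c_rel"] + params["a_rel"] * CaSR ** 2
                / (params["b_rel"] ** 2 + CaSR ** 2)) * state["d"] * state["g"] * 0.0411
        if Cai <= 0.00035:
            g_inf = 1 / (1 + (Cai / 0.00035) ** 6)
        else:
            g_inf = 1 / (1 + (Cai / 0.00035) ** 16)
        if V > -0.06 and g_inf > state["g"]:
            d_g = 0.0
        else:
            d_g = (g_inf - state["g"]) / 0.002
    else:
        sr_gate = 1 - 1 / (1 + exp((CaSR - 0.3) / 0.1))
        Irel = params["g_irel_max"] * sr_gate * state["RyRo"] * state["RyRc"] * (CaSR - Cai)
        cai_uM = Cai * 1000
        RyRa_inf = params["RyRa1"] - params["RyRa2"] \
            / (1 + exp((cai_uM - params["RyRahalf"]) / 0.0082))
        d_RyRa = (RyRa_inf - state["RyRa"]) / 1.0
        RyRo_inf = 1 - 1 / (1 + exp((cai_uM - (state["RyRa"] + params["RyRohalf"])) / 0.003))
        tau_o = 0.01875 if RyRo_inf >= state["RyRo"] else 0.001875
        d_RyRo = (RyRo_inf - state["RyRo"]) / tau_o
        RyRc_inf = 1 / (1 + exp((cai_uM - (state["RyRa"] + params["RyRchalf"])) / 0.001))
        tau_c = 0.175 if RyRc_inf >= state["RyRc"] else 0.0875
        d_RyRc = (RyRc_inf - state["RyRc"]) / tau_c

    Cm = params["Cm"]
    Vc = params["Vc"] * 1e-18
    buf_i = 1 / (1 + params["Buf_C"] * params["Kbuf_C"] / (Cai + params["Kbuf_C"]) ** 2)
    buf_sr = 1 / (1 + params["Buf_SR"] * params["Kbuf_SR"] / (CaSR + params["Kbuf_SR"]) ** 2)

    out = {
        "Vm": -(INa + INaL + ICaL + Ito + IKr + IKs + IK1 + If + INaCa + INaK
                + IpCa + IbNa + IbCa),
        "Ca_SR": buf_sr * params["Vc"] / params["V_SR"] * (Iup - Irel - Ileak),
        "Cai": buf_i * (Ileak - Iup + Irel
                        - (ICaL + IbCa + IpCa - 2 * INaCa) * Cm / (2 * Vc * F)),
        "g": d_g,
        "d": (d_inf - state["d"]) / tau_d,
        "f1": (f1_inf - state["f1"]) / tau_f1,
        "f2": (f2_inf - state["f2"]) / tau_f2,
        "fCa": k_fCa * (fCa_inf - state["fCa"]) / 0.002,
        "Xr1": (Xr1_inf - state["Xr1"]) / tau_Xr1,
        "Xr2": (Xr2_inf - state["Xr2"]) / tau_Xr2,
        "Xs": (Xs_inf - state["Xs"]) / tau_Xs,
        "h": (h_inf - state["h"]) / tau_h,
        "j": (j_inf - state["j"]) / tau_j,
        "m": (m_inf - state["m"]) / tau_m,
        "Xf": (Xf_inf - Xf) / tau_Xf,
        "q": (q_inf - state["q"]) / tau_q,
        "r": (r_inf - state["r"]) / tau_r,
        "Nai": -Cm * (INa + INaL + IbNa + 3 * INaK + 3 * INaCa + If_Na) / (F * Vc),
        "mL": (mL_inf - state["mL"]) / tau_mL,
        "hL": (hL_inf - state["hL"]) / tau_hL,
        "RyRa": d_RyRa,
        "RyRo": d_RyRo,
        "RyRc": d_RyRc,
    }
    return out
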