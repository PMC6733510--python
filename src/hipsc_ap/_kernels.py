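"""Numba-compiled right-hand sides of the Paci2017/Paci2018 hiPSC-CM models.

One kernel serves both variants (selected by ``variant_id`` in the packed
parameter vector) and all four funny-current formulations (``if_id``).  The
membrane equation is assembled from the same current values that
:func:`currents` exposes, so the identity dVm/dt == -(sum of currents) holds
at machine precision by construction.

No stimulus current exists anywhere: the models are spontaneously active.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._layout import NCURRENTS, NSTATES

# state slots (mirrors _layout.STATE_NAMES; literals so numba can constant-fold)
_VM, _CASR, _CAI, _G, _D, _F1, _F2, _FCA, _XR1, _XR2, _XS, _H, _J, _M, _XF, \
    _Q, _R, _NAI, _ML, _HL, _RYRA, _RYRO, _RYRC = range(23)

# parameter slots (mirrors _layout.PARAM_NAMES)
(_pF, _pR, _pT, _pCM, _pVC, _pVSR, _pNAO, _pKO, _pCAO, _pKI,
 _pGNA, _pGNAL, _pGCAL, _pGTO, _pGKR, _pGKS, _pGK1, _pGF,
 _pGPCA, _pGBNA, _pGBCA,
 _pKNACA, _pKMCA, _pKMNAI, _pKSAT, _pGAMMA, _pALPHA,
 _pPNAK, _pKMK, _pKMNA,
 _pKPCA,
 _pEF, _pFNAIF,
 _pVMAXUP, _pKUP, _pVLEAK,
 _pAREL, _pBREL, _pCREL,
 _pGIREL, _pRYRA1, _pRYRA2, _pRYRAH, _pRYROH, _pRYRCH,
 _pBUFC, _pKBUFC, _pBUFSR, _pKBUFSR,
 _pL0, _pQ, _pPKNA,
 _pVHHL, _pTAUHL,
 _pVARIANT, _pIFID) = range(56)


@njit(cache=True)
def _ghk_z_factor(z):
    """z / (exp(z) - 1) with the removable singularity at z = 0 expanded."""
    if abs(z) < 1e-4:
        return 1.0 - z / 2.0 + z * z / 12.0
    return z / math.expm1(z)


@njit(cache=True)
def if_gate(vmv, ifid):
    """Steady state and time constant (s) of the funny-current gate.

    ``vmv`` is the membrane potential in mV.  Formulations:
    0 native Paci, 1 Severi2012, 2 Fabbri2017, 3 Koivumaki2018 (hESC-CM
    calibrated reconstruction).
    """
    if ifid == 0:
        xinf = 1.0 / (1.0 + math.exp((vmv + 77.85) / 5.0))
        tau = 1.9 / (1.0 + math.exp((vmv + 15.0) / 10.0))
    elif ifid == 1:
        xinf = 1.0 / (1.0 + math.exp((vmv + 52.5) / 9.0))
        tau = 0.7166529 / (0.0708 * math.exp(-(vmv + 5.0) / 20.2791)
                           + 10.6 * math.exp(vmv / 18.0))
    elif ifid == 2:
        if vmv < -80.0:
            # published asymptote is 1.0125; clip to the unit interval (only
            # reached below -133 mV, outside the model's operating range)
            xinf = min(1.0, 0.01329 + 0.99921 / (1.0 + math.exp((vmv + 97.134) / 8.1752)))
        else:
            xinf = 0.0002501 * math.exp(-vmv / 12.861)
        za = 0.066 * (vmv + 148.8)
        if abs(za) < 1e-9:
            a = 0.36 / 0.066
        else:
            a = 0.36 * (vmv + 148.8) / math.expm1(za)
        zb = -0.2 * (vmv + 87.3)
        if abs(zb) < 1e-9:
            b = 0.1 / 0.2
        else:
            b = -0.1 * (vmv + 87.3) / math.expm1(zb)
        tau = 1.0 / (a + b) - 0.054
        if tau < 1e-3:
            tau = 1e-3
    else:
        xinf = 1.0 / (1.0 + math.exp((vmv + 96.9) / 8.8))
        d = (vmv + 90.0) / 30.0
        tau = 0.1 + 1.3 * math.exp(-d * d)
    return xinf, tau


@njit(cache=True)
def if_current(vm, gate, e_na, e_k, gf, e_f, fna, ifid, variant, ko):
    """Funny current (total, Na+ component) in A/F at membrane potential ``vm`` (V).

    The native 2013/2017 formulation uses a lumped reversal ``e_f``; the 2018
    revision and the split formulations carry fraction ``fna`` of the current
    as Na+ (which feeds the Na+ balance) and the rest as K+.  The Severi
    formulation keeps its extracellular-K+ dependence Ko/(Ko + 45 mM), part
    of its current equation (not of the conductance, which is the host's).
    """
    if ifid == 0:
        if variant == 0:
            return gf * gate * (vm - e_f), 0.0
        ina = fna * gf * gate * (vm - e_na)
        ik = (1.0 - fna) * gf * gate * (vm - e_k)
        return ina + ik, ina
    if ifid == 1:
        kdep = ko / (ko + 45.0)
        ina = 0.5 * gf * gate * kdep * (vm - e_na)
        ik = 0.5 * gf * gate * kdep * (vm - e_k)
        return ina + ik, ina
    if ifid == 2:
        ina = 0.42 * gf * gate * (vm - e_na)
        ik = 0.58 * gf * gate * (vm - e_k)
        return ina + ik, ina
    ina = fna * gf * gate * (vm - e_na)
    ik = (1.0 - fna) * gf * gate * (vm - e_k)
    return ina + ik, ina


@njit(cache=True)
def rhs(t, y, p, dy, cur):
    """Fill ``dy`` (state derivative) and ``cur`` (membrane currents, A/F)."""
    F = p[_pF]
    Rg = p[_pR]
    T = p[_pT]
    rtf = Rg * T / F          # V
    frt = 1.0 / rtf

    vm = y[_VM]
    vmv = vm * 1000.0
    casr = y[_CASR]
    cai = y[_CAI]
    nai = y[_NAI]
    nao = p[_pNAO]
    ko = p[_pKO]
    cao = p[_pCAO]
    ki = p[_pKI]

    e_na = rtf * math.log(nao / nai)
    e_k = rtf * math.log(ko / ki)
    e_ks = rtf * math.log((ko + p[_pPKNA] * nao) / (ki + p[_pPKNA] * nai))
    e_ca = 0.5 * rtf * math.log(cao / cai)

    # ---- INa -------------------------------------------------------------
    m = y[_M]
    i_na = p[_pGNA] * m * m * m * y[_H] * y[_J] * (vm - e_na)

    m_inf = (1.0 + math.exp((-vmv - 34.1) / 5.9)) ** (-1.0 / 3.0)
    alpha_m = 1.0 / (1.0 + math.exp((-vmv - 60.0) / 5.0))
    beta_m = 0.1 / (1.0 + math.exp((vmv + 35.0) / 5.0)) \
        + 0.1 / (1.0 + math.exp((vmv - 50.0) / 200.0))
    tau_m = alpha_m * beta_m * 1e-3

    h_inf = 1.0 / math.sqrt(1.0 + math.exp((vmv + 72.1) / 5.7))
    if vmv < -40.0:
        alpha_h = 0.057 * math.exp(-(vmv + 80.0) / 6.8)
        beta_h = 2.7 * math.exp(0.079 * vmv) + 3.1e5 * math.exp(0.3485 * vmv)
    else:
        alpha_h = 0.0
        beta_h = 0.77 / (0.13 * (1.0 + math.exp(-(vmv + 10.66) / 11.1)))
    tau_h = 1.5 / ((alpha_h + beta_h) * 1000.0)

    j_inf = h_inf
    if vmv < -40.0:
        alpha_j = (-25428.0 * math.exp(0.2444 * vmv)
                   - 6.948e-6 * math.exp(-0.04391 * vmv)) * (vmv + 37.78) \
            / (1.0 + math.exp(0.311 * (vmv + 79.23)))
        beta_j = 0.02424 * math.exp(-0.01052 * vmv) \
            / (1.0 + math.exp(-0.1378 * (vmv + 40.14)))
    else:
        alpha_j = 0.0
        beta_j = 0.6 * math.exp(0.057 * vmv) \
            / (1.0 + math.exp(-0.1 * (vmv + 32.0)))
    tau_j = 7.0 / ((alpha_j + beta_j) * 1000.0)

    # ---- INaL ------------------------------------------------------------
    ml = y[_ML]
    i_nal = p[_pGNAL] * ml * ml * ml * y[_HL] * (vm - e_na)

    ml_inf = 1.0 / (1.0 + math.exp(-(vmv + 42.85) / 5.264))
    va = vmv + 47.13
    if abs(va) < 1e-9:
        alpha_ml = 3.2
    else:
        alpha_ml = 0.32 * va / (1.0 - math.exp(-0.1 * va))
    beta_ml = 0.08 * math.exp(-vmv / 11.0)
    tau_ml = 1e-3 / (alpha_ml + beta_ml)

    hl_inf = 1.0 / (1.0 + math.exp((vmv + p[_pVHHL]) / 7.488))
    tau_hl = p[_pTAUHL]

    # ---- ICaL ------------------------------------------------------------
    z = 2.0 * vm * frt
    i_cal = p[_pGCAL] * 2.0 * F \
        * (cai * math.exp(z) - 0.341 * cao) * _ghk_z_factor(z) \
        * y[_D] * y[_F1] * y[_F2] * y[_FCA]

    d_inf = 1.0 / (1.0 + math.exp(-(vmv + 9.1) / 7.0))
    alpha_d = 0.25 + 1.4 / (1.0 + math.exp((-vmv - 35.0) / 13.0))
    beta_d = 1.4 / (1.0 + math.exp((vmv + 5.0) / 5.0))
    gamma_d = 1.0 / (1.0 + math.exp((-vmv + 50.0) / 20.0))
    tau_d = (alpha_d * beta_d + gamma_d) * 1e-3

    f1_inf = 1.0 / (1.0 + math.exp((vmv + 26.0) / 3.0))
    df1 = (vmv + 27.0) ** 2 / 15.0
    tau_f1 = (20.0 + 1102.5 * math.exp(-df1 * df1)
              + 200.0 / (1.0 + math.exp((13.0 - vmv) / 10.0))
              + 180.0 / (1.0 + math.exp((30.0 + vmv) / 10.0))) * 1e-3
    if f1_inf - y[_F1] > 0.0:
        tau_f1 = tau_f1 * (1.0 + 1433.0 * (cai - 50.0e-6))

    f2_inf = 0.33 + 0.67 / (1.0 + math.exp((vmv + 35.0) / 4.0))
    tau_f2 = (600.0 * math.exp(-(vmv + 25.0) ** 2 / 170.0)
              + 31.0 / (1.0 + math.exp((25.0 - vmv) / 10.0))
              + 16.0 / (1.0 + math.exp((30.0 + vmv) / 10.0))) * 1e-3

    alpha_fca = 1.0 / (1.0 + (cai / 0.0006) ** 8)
    beta_fca = 0.1 / (1.0 + math.exp((cai - 0.0009) / 0.0001))
    gamma_fca = 0.3 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    fca_inf = (alpha_fca + beta_fca + gamma_fca) / 1.3156
    tau_fca = 0.002
    if vm > -0.06 and fca_inf > y[_FCA]:
        const_fca = 0.0
    else:
        const_fca = 1.0

    # ---- Ito -------------------------------------------------------------
    i_to = p[_pGTO] * y[_Q] * y[_R] * (vm - e_k)
    q_inf = 1.0 / (1.0 + math.exp((vmv + 53.0) / 13.0))
    tau_q = (6.06 + 39.102 / (0.57 * math.exp(-0.08 * (vmv + 44.0))
                              + 0.065 * math.exp(0.1 * (vmv + 45.93)))) * 1e-3
    r_inf = 1.0 / (1.0 + math.exp(-(vmv - 22.3) / 18.75))
    tau_r = (2.75352 + 14.40516 / (1.037 * math.exp(0.09 * (vmv + 30.61))
                                   + 0.369 * math.exp(-0.12 * (vmv + 23.84)))) * 1e-3

    # ---- IKr -------------------------------------------------------------
    i_kr = p[_pGKR] * math.sqrt(ko / 5.4) * y[_XR1] * y[_XR2] * (vm - e_k)
    v_half = 1000.0 * (-rtf / p[_pQ]
                       * math.log((1.0 + cao / 2.6) ** 4
                                  / (p[_pL0] * (1.0 + cao / 0.58) ** 4))
                       - 0.019)
    xr1_inf = 1.0 / (1.0 + math.exp((v_half - vmv) / 4.9))
    alpha_xr1 = 450.0 / (1.0 + math.exp((-45.0 - vmv) / 10.0))
    beta_xr1 = 6.0 / (1.0 + math.exp((30.0 + vmv) / 11.5))
    tau_xr1 = alpha_xr1 * beta_xr1 * 1e-3
    xr2_inf = 1.0 / (1.0 + math.exp((vmv + 88.0) / 50.0))
    alpha_xr2 = 3.0 / (1.0 + math.exp((-60.0 - vmv) / 20.0))
    beta_xr2 = 1.12 / (1.0 + math.exp((-60.0 + vmv) / 20.0))
    tau_xr2 = alpha_xr2 * beta_xr2 * 1e-3

    # ---- IKs -------------------------------------------------------------
    xs = y[_XS]
    i_ks = p[_pGKS] * xs * xs * (vm - e_ks) \
        * (1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4))
    xs_inf = 1.0 / (1.0 + math.exp((-vmv - 20.0) / 16.0))
    alpha_xs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - vmv) / 6.0))
    beta_xs = 1.0 / (1.0 + math.exp((-60.0 + vmv) / 20.0))
    tau_xs = alpha_xs * beta_xs * 1e-3

    # ---- IK1 -------------------------------------------------------------
    dvk = vmv - e_k * 1000.0
    alpha_k1 = 3.91 / (1.0 + math.exp(0.5942 * (dvk - 200.0)))
    beta_k1 = (-1.509 * math.exp(0.0002 * (dvk + 100.0))
               + math.exp(0.5886 * (dvk - 10.0))) \
        / (1.0 + math.exp(0.4547 * dvk))
    xk1_inf = alpha_k1 / (alpha_k1 + beta_k1)
    i_k1 = p[_pGK1] * math.sqrt(ko / 5.4) * xk1_inf * (vm - e_k)

    # ---- If --------------------------------------------------------------
    ifid = int(p[_pIFID])
    i_f, i_f_na = if_current(vm, y[_XF], e_na, e_k, p[_pGF], p[_pEF],
                             p[_pFNAIF], ifid, int(p[_pVARIANT]), ko)
    xf_inf, tau_xf = if_gate(vmv, ifid)

    # ---- pumps, exchanger, background ------------------------------------
    gam = p[_pGAMMA]
    i_naca = p[_pKNACA] \
        * (math.exp(gam * vm * frt) * nai ** 3 * cao
           - math.exp((gam - 1.0) * vm * frt) * nao ** 3 * cai * p[_pALPHA]) \
        / ((p[_pKMNAI] ** 3 + nao ** 3) * (p[_pKMCA] + cao)
           * (1.0 + p[_pKSAT] * math.exp((gam - 1.0) * vm * frt)))

    i_nak = p[_pPNAK] * ko / (ko + p[_pKMK]) * nai / (nai + p[_pKMNA]) \
        / (1.0 + 0.1245 * math.exp(-0.1 * vm * frt)
           + 0.0353 * math.exp(-vm * frt))

    i_pca = p[_pGPCA] * cai / (cai + p[_pKPCA])
    i_b_na = p[_pGBNA] * (vm - e_na)
    i_b_ca = p[_pGBCA] * (vm - e_ca)

    cur[0] = i_na
    cur[1] = i_nal
    cur[2] = i_cal
    cur[3] = i_to
    cur[4] = i_kr
    cur[5] = i_ks
    cur[6] = i_k1
    cur[7] = i_f
    cur[8] = i_naca
    cur[9] = i_nak
    cur[10] = i_pca
    cur[11] = i_b_na
    cur[12] = i_b_ca

    # ---- SR calcium fluxes (variant-specific release) --------------------
    variant = int(p[_pVARIANT])
    i_up = p[_pVMAXUP] / (1.0 + (p[_pKUP] / cai) ** 2)
    i_leak = (casr - cai) * p[_pVLEAK]

    dy[_G] = 0.0
    dy[_RYRA] = 0.0
    dy[_RYRO] = 0.0
    dy[_RYRC] = 0.0
    if variant == 0:
        # 2013-style release with Ca-dependent inactivation gate g
        i_rel = (p[_pCREL] + p[_pAREL] * casr * casr
                 / (p[_pBREL] * p[_pBREL] + casr * casr)) \
            * y[_D] * y[_G] * 0.0411
        if cai <= 0.00035:
            g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
        else:
            g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
        if vm > -0.06 and g_inf > y[_G]:
            const_g = 0.0
        else:
            const_g = 1.0
        dy[_G] = const_g * (g_inf - y[_G]) / 0.002
    else:
        # Paci2018 RyR-gated release
        ryr_sr = 1.0 - 1.0 / (1.0 + math.exp((casr - 0.3) / 0.1))
        i_rel = p[_pGIREL] * ryr_sr * y[_RYRO] * y[_RYRC] * (casr - cai)
        cai_um = cai * 1000.0
        ryra_inf = p[_pRYRA1] - p[_pRYRA2] \
            / (1.0 + math.exp((cai_um - p[_pRYRAH]) / 0.0082))
        dy[_RYRA] = (ryra_inf - y[_RYRA]) / 1.0
        ryro_inf = 1.0 - 1.0 / (1.0 + math.exp((cai_um - (y[_RYRA] + p[_pRYROH])) / 0.003))
        if ryro_inf >= y[_RYRO]:
            tau_o = 0.01875
        else:
            tau_o = 0.1 * 0.01875
        dy[_RYRO] = (ryro_inf - y[_RYRO]) / tau_o
        ryrc_inf = 1.0 / (1.0 + math.exp((cai_um - (y[_RYRA] + p[_pRYRCH])) / 0.001))
        if ryrc_inf >= y[_RYRC]:
            tau_c = 2.0 * 0.0875
        else:
            tau_c = 0.0875
        dy[_RYRC] = (ryrc_inf - y[_RYRC]) / tau_c

    # ---- balances --------------------------------------------------------
    cm = p[_pCM]
    vc_m3 = p[_pVC] * 1e-18
    vsr_m3 = p[_pVSR] * 1e-18

    cai_buf = 1.0 / (1.0 + p[_pBUFC] * p[_pKBUFC] / (cai + p[_pKBUFC]) ** 2)
    casr_buf = 1.0 / (1.0 + p[_pBUFSR] * p[_pKBUFSR] / (casr + p[_pKBUFSR]) ** 2)

    dy[_CAI] = cai_buf * (i_leak - i_up + i_rel
                          - (i_cal + i_b_ca + i_pca - 2.0 * i_naca)
                          * cm / (2.0 * vc_m3 * F))
    dy[_CASR] = casr_buf * (p[_pVC] / p[_pVSR]) * (i_up - i_rel - i_leak)
    dy[_NAI] = -cm * (i_na + i_nal + i_b_na + 3.0 * i_nak + 3.0 * i_naca
                      + i_f_na) / (F * vc_m3)

    total = i_na + i_nal + i_cal + i_to + i_kr + i_ks + i_k1 + i_f \
        + i_naca + i_nak + i_pca + i_b_na + i_b_ca
    dy[_VM] = -total

    dy[_D] = (d_inf - y[_D]) / tau_d
    dy[_F1] = (f1_inf - y[_F1]) / tau_f1
    dy[_F2] = (f2_inf - y[_F2]) / tau_f2
    dy[_FCA] = const_fca * (fca_inf - y[_FCA]) / tau_fca
    dy[_XR1] = (xr1_inf - y[_XR1]) / tau_xr1
    dy[_XR2] = (xr2_inf - y[_XR2]) / tau_xr2
    dy[_XS] = (xs_inf - y[_XS]) / tau_xs
    dy[_H] = (h_inf - y[_H]) / tau_h
    dy[_J] = (j_inf - y[_J]) / tau_j
    dy[_M] = (m_inf - y[_M]) / tau_m
    dy[_XF] = (xf_inf - y[_XF]) / tau_xf
    dy[_Q] = (q_inf - y[_Q]) / tau_q
    dy[_R] = (r_inf - y[_R]) / tau_r
    dy[_ML] = (ml_inf - y[_ML]) / tau_ml
    dy[_HL] = (hl_inf - y[_HL]) / tau_hl


@njit(cache=True)
def rhs_ivp(t, y, p):
    """Allocation-per-call wrapper with the (t, y, p) signature solve_ivp wants."""
    dy = np.empty(NSTATES)
    cur = np.empty(NCURRENTS)
    rhs(t, y, p, dy, cur)
    return dy


@njit(cache=True)
def fill_traces(ts, ys, p, dvdt, currents):
    """Evaluate dVm/dt and the current set at each output sample.

    ``ys`` is (n, NSTATES); ``dvdt`` (n,) and ``currents`` (n, NCURRENTS)
    are filled in place.  Evaluating the right-hand side at the samples keeps
    the upstroke-velocity trace independent of the output grid.
    """
    dy = np.empty(NSTATES)
    cur = np.empty(NCURRENTS)
    for i in range(ts.shape[0]):
        rhs(ts[i], ys[i], p, dy, cur)
        dvdt[i] = dy[0]
        for k in range(NCURRENTS):
            currents[i, k] = cur[k]
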