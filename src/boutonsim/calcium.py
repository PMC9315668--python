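"""Compartmental Ca2+ dynamics and IP3 metabolism of the bouton.

Four Ca2+ state variables are integrated: bulk cytosol (Ca_cyt), the
microdomain around the IP3R cluster (Ca_IPRn), the active-zone microdomain
around the VGCC cluster (Ca_AZ), and the whole-terminal total (Ca_total).
The ER concentration is algebraic:

    Ca_ER = delta2 * (Ca_total - Ca_cyt + Ca_IPRn/delta1 - Ca_AZ)

All fluxes are expressed per cytosolic volume; the volume ratios delta1
(IP3R microdomain) and delta3 (AZ microdomain) convert them to microdomain
concentration rates in the respective balance equations:

    dCa_cyt/dt   = Jin + JIPR_diff - JPMCA + JER_leak + JVGCC_diff - JSERCA
    dCa_IPRn/dt  = delta1 (JIPR - JIPR_diff) + Jcoupling
    dCa_AZ/dt    = delta3 (JVGCC - JVGCC_diff) - Jcoupling/delta1
    dCa_total/dt = Jin - JPMCA + JVGCC

The ER-AZ coupling flux is a bidirectional, saturating transfer analogous
to reversible SERCA pump models; it stands in for buffered Ca2+ diffusion
between the two microdomains.  IP3 metabolism combines PLC-delta
production (with an optional amyloid-beta-driven G-protein cascade) and
degradation by 3-kinase and 5-phosphatase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import (CalciumParams, CouplingParams, IP3MetabolismParams,
                     ParameterSet,
                     i_JLEAK_IN, i_VLEAK_IN, i_K_IPR_DIFF, i_K_VGCC_DIFF,
                     i_K_ER_LEAK, i_K_IPR, i_V_PMCA, i_K_PMCA, i_N_P,
                     i_V_SERCA, i_K_SERCA, i_N_S, i_D1, i_D2, i_D3,
                     i_VC, i_KBAR, i_KC, i_COUP_PRINTED,
                     i_V0, i_VQ, i_KQ, i_K_IP3K, i_K_PLC, i_K3K, i_K5P,
                     i_KF_PLC, i_KB_PLC, i_PLC_TOT, i_KF_G, i_KB_G,
                     i_DELTA_G, i_VR, i_KR, i_G_TOT, i_ABETA, i_ABETA_R,
                     i_ABETA_T1)


@dataclass
class CalciumState:
    Ca_cyt: float = 0.1      # uM
    Ca_IPRn: float = 0.1     # uM
    Ca_AZ: float = 0.05      # uM
    Ca_total: float = 56.0   # uM
    IP3: float = 0.1         # uM
    PLC: float = 0.0         # scaled activity in [0, PLC_tot]
    G: float = 0.0           # scaled activity in [0, G_tot]

    def Ca_ER(self, ca: CalciumParams) -> float:
        return ca.delta2 * (self.Ca_total - self.Ca_cyt
                            + self.Ca_IPRn / ca.delta1 - self.Ca_AZ)


@dataclass
class FluxSet:
    Jin: float
    JIPR: float
    JIPR_diff: float
    JPMCA: float
    JSERCA: float
    JER_leak: float
    JVGCC: float
    JVGCC_diff: float
    Jcoupling: float


@njit(cache=True)
def _hill_flux(ca, vmax, K, n):
    if ca <= 0.0:        # guard: fractional powers of negative substep values
        return 0.0
    cn = ca ** n
    return vmax * cn / (cn + K ** n)


@njit(cache=True)
def _ca_er(ca_cyt, ca_iprn, ca_az, ca_total, cp):
    return cp[i_D2] * (ca_total - ca_cyt + ca_iprn / cp[i_D1] - ca_az)


@njit(cache=True)
def _coupling_flux(ca_az, ca_iprn, kp):
    num = ca_az * ca_az - kp[i_KBAR] * ca_iprn * ca_iprn
    kc2 = kp[i_KC] * kp[i_KC]
    if kp[i_COUP_PRINTED] != 0.0:
        den = ca_az * ca_az - kc2
        if abs(den) < 1e-3:          # guard band around the printed pole
            den = 1e-3 if den >= 0 else -1e-3
    else:
        den = ca_az * ca_az + kc2
    return kp[i_VC] * num / den


def coupling_flux(Ca_AZ: float, Ca_IPRn: float,
                  coupling: CouplingParams) -> float:
    """Bidirectional ER-AZ transfer flux (uM/ms, positive = AZ -> IP3R side).

    Zero when Ca_AZ^2 = kbar * Ca_IPRn^2; the sign reverses across that
    surface.  The default denominator is the saturating Ca_AZ^2 + Kc^2; the
    printed difference form is available via
    ``CouplingParams.printed_denominator`` (with a guard band at the pole).
    """
    if Ca_AZ < 0 or Ca_IPRn < 0:
        raise ValueError("concentrations must be >= 0")
    return float(_coupling_flux(float(Ca_AZ), float(Ca_IPRn),
                                coupling.as_array()))


@njit(cache=True)
def _fluxes(ca_cyt, ca_iprn, ca_az, ca_total, ip3, po_ipr, j_vgcc, cp, kp):
    """All nine fluxes in uM/ms (per cytosolic volume).

    Inputs are clamped at zero: RK4 substages may probe slightly negative
    concentrations, and the algebraic ER expression can transiently dip
    below zero while the AZ microdomain holds a large Ca2+ load.
    """
    if ca_cyt < 0.0:
        ca_cyt = 0.0
    if ca_iprn < 0.0:
        ca_iprn = 0.0
    if ca_az < 0.0:
        ca_az = 0.0
    ca_er = _ca_er(ca_cyt, ca_iprn, ca_az, ca_total, cp)
    if ca_er < 0.0:
        ca_er = 0.0
    jin = cp[i_JLEAK_IN] + cp[i_VLEAK_IN] * ip3
    jipr = cp[i_K_IPR] * po_ipr * (ca_er - ca_iprn)
    jipr_diff = cp[i_K_IPR_DIFF] * (ca_iprn - ca_cyt)
    jpmca = _hill_flux(ca_cyt, cp[i_V_PMCA], cp[i_K_PMCA], cp[i_N_P])
    jserca = _hill_flux(ca_cyt, cp[i_V_SERCA], cp[i_K_SERCA], cp[i_N_S])
    jer_leak = cp[i_K_ER_LEAK] * (ca_er - ca_cyt)
    jvgcc_diff = cp[i_K_VGCC_DIFF] * (ca_az - ca_cyt)
    jcoup = _coupling_flux(ca_az, ca_iprn, kp)
    return (jin, jipr, jipr_diff, jpmca, jserca, jer_leak, j_vgcc,
            jvgcc_diff, jcoup)


def compute_fluxes(state: CalciumState, Po_IPR: float, J_VGCC: float,
                   params: ParameterSet) -> FluxSet:
    """Evaluate every Ca2+ flux at the given state.

    ``Po_IPR`` is the IP3R-cluster open fraction and ``J_VGCC`` the VGCC
    influx (uM/ms per cytosolic volume) computed by the VGCC module.
    """
    if min(state.Ca_cyt, state.Ca_IPRn, state.Ca_AZ) < 0:
        raise ValueError("negative concentration input")
    if not 0.0 <= Po_IPR <= 1.0:
        raise ValueError(f"Po_IPR must lie in [0,1], got {Po_IPR}")
    f = _fluxes(state.Ca_cyt, state.Ca_IPRn, state.Ca_AZ, state.Ca_total,
                state.IP3, Po_IPR, J_VGCC,
                params.calcium.as_array(), params.coupling_params.as_array())
    return FluxSet(Jin=f[0], JIPR=f[1], JIPR_diff=f[2], JPMCA=f[3],
                   JSERCA=f[4], JER_leak=f[5], JVGCC=f[6], JVGCC_diff=f[7],
                   Jcoupling=f[8])


@njit(cache=True)
def _calcium_rhs(ca_cyt, ca_iprn, ca_az, ca_total, ip3, po_ipr, j_vgcc,
                 cp, kp):
    (jin, jipr, jipr_diff, jpmca, jserca, jer_leak, jv, jvgcc_diff,
     jcoup) = _fluxes(ca_cyt, ca_iprn, ca_az, ca_total, ip3, po_ipr,
                      j_vgcc, cp, kp)
    d_cyt = jin + jipr_diff - jpmca + jer_leak + jvgcc_diff - jserca
    d_iprn = cp[i_D1] * (jipr - jipr_diff) + jcoup
    d_az = cp[i_D3] * (jv - jvgcc_diff) - jcoup / cp[i_D1]
    d_total = jin - jpmca + jv
    return d_cyt, d_iprn, d_az, d_total


def calcium_rhs(state: CalciumState, fluxes: FluxSet,
                params: ParameterSet):
    """Time derivatives of (Ca_cyt, Ca_IPRn, Ca_AZ, Ca_total) in uM/ms."""
    cp = params.calcium
    f = fluxes
    d_cyt = (f.Jin + f.JIPR_diff - f.JPMCA + f.JER_leak + f.JVGCC_diff
             - f.JSERCA)
    d_iprn = cp.delta1 * (f.JIPR - f.JIPR_diff) + f.Jcoupling
    d_az = cp.delta3 * (f.JVGCC - f.JVGCC_diff) - f.Jcoupling / cp.delta1
    d_total = f.Jin - f.JPMCA + f.JVGCC
    return d_cyt, d_iprn, d_az, d_total


@njit(cache=True)
def _abeta_q(t, mp):
    """Amyloid-beta input q(t) = Abeta * exp(-r (t - t1)) * H(t - t1)."""
    if mp[i_ABETA] <= 0.0 or t < mp[i_ABETA_T1]:
        return 0.0
    return mp[i_ABETA] * np.exp(-mp[i_ABETA_R] * (t - mp[i_ABETA_T1]))


@njit(cache=True)
def _ip3_rhs(ip3, plc, g, ca_cyt, t, mp):
    """(dIP3/dt, dPLC/dt, dG/dt)."""
    q = _abeta_q(t, mp)
    vplc = mp[i_V0] + mp[i_VQ] * q * q / (q * q + mp[i_KQ] * mp[i_KQ])
    vbar = vplc * plc
    c2 = ca_cyt * ca_cyt
    jplc = vbar * c2 / (c2 + mp[i_K_PLC] * mp[i_K_PLC])
    eta = mp[i_K3K] / (mp[i_K3K] + mp[i_K5P])
    jdeg = (eta * c2 / (c2 + mp[i_K_IP3K] * mp[i_K_IP3K]) + (1.0 - eta)) * ip3
    tau = 1.0 / (mp[i_K3K] + mp[i_K5P])
    rho = mp[i_VR] * q / (q + mp[i_KR])
    dplc = mp[i_KF_PLC] * g * (mp[i_PLC_TOT] - plc) - mp[i_KB_PLC] * plc
    dg = mp[i_KF_G] * (rho + mp[i_DELTA_G]) * (mp[i_G_TOT] - g) \
        - mp[i_KB_G] * g
    return (jplc - jdeg) / tau, dplc, dg


def ip3_rhs(state: CalciumState, t: float,
            params: IP3MetabolismParams):
    """(dIP3/dt, dPLC/dt, dG/dt) at time ``t`` (ms, for the Abeta input)."""
    return _ip3_rhs(state.IP3, state.PLC, state.G, state.Ca_cyt, float(t),
                    params.as_array())


def plc_g_fixed_point(params: IP3MetabolismParams) -> tuple[float, float]:
    """Steady-state (PLC, G) activities with no amyloid-beta input."""
    g = params.kf_G * params.delta_G * params.G_tot / (
        params.kf_G * params.delta_G + params.kb_G)
    plc = params.kf_PLC * g * params.PLC_tot / (params.kf_PLC * g
                                                + params.kb_PLC)
    return plc, g
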