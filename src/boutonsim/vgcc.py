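"""Five-state Cav2.1 (P/Q-type) voltage-gated Ca2+ channel.

Linear gating chain C1 <-> C2 <-> C3 <-> C4 <-> O with voltage-dependent
rates alpha_i(V) = alpha_i0 exp(V/k_i) (activation, forward) and
beta_i(V) = beta_i0 exp(-V/k_i) (deactivation, backward).  Only the open
state conducts; there is no inactivation.  The single-channel current is
ohmic, Is = g * Po * (V - E_Ca), and the whole-cluster Ca2+ flux into the
active-zone microdomain follows from the channel density over the AZ and
the 25 nm cluster geometry.

State encoding: 0..3 = C1..C4, 4 = O.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import (VGCCParams, i_AL1, i_BE1, i_KV1, i_G_VGCC, i_E_CA,
                     i_CLUSTER_AREA, i_AZ_AREA, i_N_AZ, i_V_EFF, i_Z_CA,
                     i_FARADAY)

N_STATES = 5
OPEN_STATE = 4


@njit(cache=True)
def _rates(v, p):
    """alpha1..4, beta1..4 at membrane potential v (mV), in ms^-1."""
    out = np.empty(8)
    for i in range(4):
        k = p[i_KV1 + i]
        out[i] = p[i_AL1 + i] * np.exp(v / k)
        out[4 + i] = p[i_BE1 + i] * np.exp(-v / k)
    return out


def vgcc_rates(V: float, params: VGCCParams) -> tuple[np.ndarray, np.ndarray]:
    """(alpha, beta) arrays of the four transitions at voltage ``V`` (mV)."""
    if not np.isfinite(V):
        raise ValueError(f"V must be finite, got {V}")
    r = _rates(float(V), params.as_array())
    return r[:4].copy(), r[4:].copy()


def generator_matrix(V: float, params: VGCCParams) -> np.ndarray:
    """5x5 CTMC generator of the gating chain at clamped voltage."""
    a, b = vgcc_rates(V, params)
    Q = np.zeros((N_STATES, N_STATES))
    for i in range(4):
        Q[i, i + 1] = a[i]
        Q[i + 1, i] = b[i]
    for i in range(N_STATES):
        Q[i, i] = -Q[i].sum()
    return Q


def stationary_distribution(V: float, params: VGCCParams) -> np.ndarray:
    """Stationary occupancy of the five states at clamped voltage.

    The chain is a reversible birth-death chain, so the distribution is
    the normalised product of alpha_i/beta_i ratios.
    """
    a, b = vgcc_rates(V, params)
    w = np.ones(N_STATES)
    for i in range(4):
        w[i + 1] = w[i] * a[i] / b[i]
    return w / w.sum()


@njit(cache=True)
def _simulate_cluster(v_trace, p, n_channels, dt, n_steps, seed):
    np.random.seed(seed)
    states = np.zeros((n_steps + 1, n_channels), dtype=np.int8)
    cur = np.zeros(n_channels, dtype=np.int8)
    for i in range(n_steps):
        v = v_trace[min(i, len(v_trace) - 1)]
        r = _rates(v, p)
        for c in range(n_channels):
            s = cur[c]
            pf = r[s] * dt if s < 4 else 0.0
            pb = r[4 + s - 1] * dt if s > 0 else 0.0
            if pf + pb >= 1.0:
                states[i + 1 :, :] = -1
                return states
            u = np.random.random()
            if u < pf:
                cur[c] = s + 1
            elif u < pf + pb:
                cur[c] = s - 1
        states[i + 1] = cur
    return states


def simulate_cluster(V_trace, N_VGCC: int, dt: float, seed: int,
                     params: VGCCParams, T: float | None = None):
    """DTMC simulation of ``N_VGCC`` independent channels.

    ``V_trace`` may be a scalar (voltage clamp) or an array on the dt grid;
    for a scalar, ``T`` (ms) sets the duration.  Returns a tuple
    ``(times, states, open_fraction)`` with ``states`` of shape
    ``(n_steps+1, N_VGCC)``.  Reproducible under fixed seed.
    """
    v = np.atleast_1d(np.asarray(V_trace, dtype=np.float64))
    if v.size == 1:
        if T is None:
            raise ValueError("T required for a clamped (scalar) V_trace")
        n_steps = int(round(T / dt))
    else:
        n_steps = v.size - 1
    p = params.as_array()
    worst = 0.0
    for vv in (v.min(), v.max()):
        r = _rates(float(vv), p)
        for s in range(N_STATES):
            ex = (r[s] if s < 4 else 0.0) + (r[4 + s - 1] if s > 0 else 0.0)
            worst = max(worst, ex)
    if worst * dt >= 1.0:
        raise ValueError(
            f"transition probability rate*dt = {worst * dt:.3g} >= 1; "
            f"use dt < {1.0 / worst:.3g} ms")
    states = _simulate_cluster(v, p, N_VGCC, dt, n_steps, np.uint32(seed))
    if states[-1, 0] < 0:
        raise ValueError("transition probability overflow; reduce dt")
    times = np.arange(n_steps + 1) * dt
    open_fraction = (states == OPEN_STATE).mean(axis=1)
    return times, states, open_fraction


@njit(cache=True)
def _single_channel_current(v, po, p):
    """Is in pA: g [pS] * Po * (V - E_Ca) [mV] * 1e-3."""
    return p[i_G_VGCC] * po * (v - p[i_E_CA]) * 1e-3


def single_channel_current(V: float, Po: float, params: VGCCParams) -> float:
    """Open-probability-weighted single-channel current (pA, inward < 0)."""
    if not 0.0 <= Po <= 1.0:
        raise ValueError(f"Po must lie in [0, 1], got {Po}")
    return float(_single_channel_current(float(V), float(Po),
                                         params.as_array()))


@njit(cache=True)
def _cluster_current(v, po, n_vgcc, p):
    """Whole-cluster Ca2+ current I_Ca in pA (inward < 0).

    I_Ca = channel density * cluster area * Is with
    density = N_VGCC / (AZ_area * N_AZ).
    """
    density = n_vgcc / (p[i_AZ_AREA] * p[i_N_AZ])
    return density * p[i_CLUSTER_AREA] * _single_channel_current(v, po, p)


@njit(cache=True)
def _flux_from_current(i_ca_pA, p):
    """J_VGCC in uM/ms (per cytosolic volume) from I_Ca in pA.

    J = -I_Ca / (z F V_eff); with I in pA (1e-12 A) and V_eff in litres the
    raw value is in 1e-12 mol/(L s) = 1e-6 uM/ms * 1e-3 ... combined scale:
    pA / (C/mol * L) = 1e-12 mol/(L*s) = 1e-12 * 1e6 uM/s = 1e-9 uM/ms.
    """
    return -i_ca_pA * 1e-12 / (p[i_Z_CA] * p[i_FARADAY] * p[i_V_EFF]) * 1e3

# note on the scale factor: I[A]/(zF[C/mol] V[L]) is mol L^-1 s^-1 = M/s;
# 1 M/s = 1e6 uM / 1e3 ms = 1e3 uM/ms, and I[A] = I[pA]*1e-12.


def vgcc_flux(Is: float, params: VGCCParams,
              N_VGCC: int | None = None) -> float:
    """Ca2+ flux into the AZ compartment (uM/ms, per cytosolic volume).

    ``Is`` is the single-channel current in pA (inward negative).  The flux
    is positive for inward current: Ca2+ is added to the AZ microdomain
    once the balance equation scales it by the volume ratio delta3.
    """
    p = params.as_array()
    n = params.N_VGCC if N_VGCC is None else N_VGCC
    density = n / (p[i_AZ_AREA] * p[i_N_AZ])
    i_ca = density * p[i_CLUSTER_AREA] * Is
    return float(_flux_from_current(i_ca, p))


def flux_at(V: float, Po: float, params: VGCCParams,
            N_VGCC: int | None = None) -> float:
    """Convenience: J_VGCC directly from voltage and cluster open fraction."""
    return vgcc_flux(single_channel_current(V, Po, params), params, N_VGCC)
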