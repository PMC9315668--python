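"""Vesicle pools, dual Ca2+ sensors and fusion (exocytosis).

Vesicle cycle:  reserve (R) <-> docked unprimed (U) <-> primed,
channel-detached (V, the slow-releasing pool) <-> primed, channel-attached
(W, the fast-releasing pool).  Mobilisation and priming are Ca_cyt
dependent; channel attachment is Ca_AZ dependent.  Primed vesicles occupy
release sites (N_sites total); a site that has just released is refractory
and recovers at rate kRF, during which it cannot accept a newly primed
vesicle.

Each primed vesicle carries a dual Ca2+ sensor: a fast synchronous sensor
S with five binding sites (on-rate alpha*Ca, off-rate m*beta*b^(m-1) with
cooperativity b) and a slow asynchronous sensor A with two binding sites
(lambda, delta, same b).  Fusion hazards: gamma2 from any state with the S
sensor full (m = 5, synchronous), gamma3 = a*gamma2 with the A sensor full
(n = 2, asynchronous), gamma1 from the ligand-free state (0,0)
(spontaneous).  V-pool sensors read Ca_cyt; W-pool sensors read Ca_AZ; a
vesicle keeps its sensor occupancy across V<->W transitions.

Two execution modes share these rate definitions: deterministic
mass-action occupancy ODEs over the 6x3 sensor grid (this module, used for
rate profiles and expectations) and a stochastic per-vesicle jump process
(the hybrid simulation kernel, used for event logs).

Deterministic state vector layout (length 42):
  [0] R, [1] U, [2:20] V grid (index m*3+n), [20:38] W grid,
  [38] refractory sites F, [39:42] cumulative sync/async/spont releases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import (ReleaseParams,
                     i_KMOB, i_KDEMOB, i_KPRIMING, i_KUNPR, i_KATTACH,
                     i_KDETACH, i_KRF, i_S_ALPHA, i_S_BETA, i_A_LAMBDA,
                     i_A_DELTA, i_GAMMA1, i_GAMMA2, i_A_RATIO, i_B_COOP,
                     i_N_SITES, i_N_RESERVE)

N_REL_STATE = 42
IDX_R, IDX_U, IDX_V0, IDX_W0, IDX_F = 0, 1, 2, 20, 38
IDX_CUM_S, IDX_CUM_A, IDX_CUM_SP = 39, 40, 41


@njit(cache=True)
def _hazards(m, n, rp):
    """Fusion hazard (ms^-1) of sensor state (m, n), split by mode."""
    hs = rp[i_GAMMA2] if m == 5 else 0.0
    ha = rp[i_A_RATIO] * rp[i_GAMMA2] if n == 2 else 0.0
    hsp = rp[i_GAMMA1] if (m == 0 and n == 0) else 0.0
    return hs, ha, hsp


@njit(cache=True)
def _sensor_rates(m, n, ca, rp):
    """(S-on, S-off, A-on, A-off) rates out of state (m, n) at drive ca."""
    s_on = (5 - m) * rp[i_S_ALPHA] * ca
    s_off = m * rp[i_S_BETA] * rp[i_B_COOP] ** (m - 1) if m > 0 else 0.0
    a_on = (2 - n) * rp[i_A_LAMBDA] * ca
    a_off = n * rp[i_A_DELTA] * rp[i_B_COOP] ** (n - 1) if n > 0 else 0.0
    return s_on, s_off, a_on, a_off


@njit(cache=True)
def _release_rates(y, rp):
    """Instantaneous (sync, async, spont) release rates of the whole pool."""
    rs = 0.0
    ra = 0.0
    g3 = rp[i_A_RATIO] * rp[i_GAMMA2]
    for n in range(3):
        rs += rp[i_GAMMA2] * (y[IDX_V0 + 15 + n] + y[IDX_W0 + 15 + n])
    for m in range(6):
        ra += g3 * (y[IDX_V0 + m * 3 + 2] + y[IDX_W0 + m * 3 + 2])
    rsp = rp[i_GAMMA1] * (y[IDX_V0] + y[IDX_W0])
    return rs, ra, rsp


@njit(cache=True)
def _release_rhs(y, ca_cyt, ca_az, rp, out):
    """Mass-action derivatives of the 42-component release state."""
    n_sites = rp[i_N_SITES]
    for i in range(N_REL_STATE):
        out[i] = 0.0
    v_tot = 0.0
    w_tot = 0.0
    for i in range(18):
        v_tot += y[IDX_V0 + i]
        w_tot += y[IDX_W0 + i]
    free = n_sites - v_tot - w_tot - y[IDX_F]
    if free < 0.0:
        free = 0.0

    mob = rp[i_KMOB] * ca_cyt * y[IDX_R]
    demob = rp[i_KDEMOB] * y[IDX_U]
    prime = rp[i_KPRIMING] * ca_cyt * y[IDX_U] * (free / n_sites)
    out[IDX_R] = -mob + demob
    out[IDX_U] = mob - demob - prime + rp[i_KUNPR] * v_tot
    out[IDX_V0] += prime        # newly primed vesicles enter V at (0, 0)

    fusion_tot = 0.0
    for m in range(6):
        for n in range(3):
            i = m * 3 + n
            yv = y[IDX_V0 + i]
            yw = y[IDX_W0 + i]
            # sensor kinetics, V pool driven by Ca_cyt
            s_on, s_off, a_on, a_off = _sensor_rates(m, n, ca_cyt, rp)
            out[IDX_V0 + i] -= (s_on + s_off + a_on + a_off) * yv
            if m < 5:
                out[IDX_V0 + i + 3] += s_on * yv
            if m > 0:
                out[IDX_V0 + i - 3] += s_off * yv
            if n < 2:
                out[IDX_V0 + i + 1] += a_on * yv
            if n > 0:
                out[IDX_V0 + i - 1] += a_off * yv
            # sensor kinetics, W pool driven by Ca_AZ
            s_on, s_off, a_on, a_off = _sensor_rates(m, n, ca_az, rp)
            out[IDX_W0 + i] -= (s_on + s_off + a_on + a_off) * yw
            if m < 5:
                out[IDX_W0 + i + 3] += s_on * yw
            if m > 0:
                out[IDX_W0 + i - 3] += s_off * yw
            if n < 2:
                out[IDX_W0 + i + 1] += a_on * yw
            if n > 0:
                out[IDX_W0 + i - 1] += a_off * yw
            # V <-> W conversion (sensor occupancy carried over)
            att = rp[i_KATTACH] * ca_az * yv
            det = rp[i_KDETACH] * yw
            out[IDX_V0 + i] += det - att
            out[IDX_W0 + i] += att - det
            # unpriming V -> U
            out[IDX_V0 + i] -= rp[i_KUNPR] * yv
            # fusion
            hs, ha, hsp = _hazards(m, n, rp)
            h = hs + ha + hsp
            if h > 0.0:
                fv = h * yv
                fw = h * yw
                out[IDX_V0 + i] -= fv
                out[IDX_W0 + i] -= fw
                fusion_tot += fv + fw
                if hs > 0.0:
                    out[IDX_CUM_S] += hs * (yv + yw)
                if ha > 0.0:
                    out[IDX_CUM_A] += ha * (yv + yw)
                if hsp > 0.0:
                    out[IDX_CUM_SP] += hsp * (yv + yw)
    out[IDX_F] = fusion_tot - rp[i_KRF] * y[IDX_F]
    return out


def initial_release_state(params: ReleaseParams, *,
                          full_priming: bool = True) -> np.ndarray:
    """Default initial pools: reserve, docked and a fully primed RRP.

    The RRP (V + W = N_sites) is split between the detached and attached
    pools according to the resting attach/detach balance; sensors start
    ligand-free.  U starts at its mobilisation balance with the reserve at
    resting Ca_cyt = 0.1 uM.
    """
    y = np.zeros(N_REL_STATE)
    y[IDX_R] = params.N_reserve
    y[IDX_U] = params.kmob * 0.1 * params.N_reserve / params.kdemob
    if full_priming:
        ratio_w = params.kattach * 0.05 / params.kdetach  # at resting Ca_AZ
        w0 = params.N_sites * ratio_w / (1.0 + ratio_w)
        y[IDX_W0] = w0
        y[IDX_V0] = params.N_sites - w0
    return y


def pool_totals(y: np.ndarray) -> dict:
    """Summed pool occupancies of a release-state vector."""
    return {
        "R": float(y[IDX_R]),
        "U": float(y[IDX_U]),
        "V": float(y[IDX_V0:IDX_V0 + 18].sum()),
        "W": float(y[IDX_W0:IDX_W0 + 18].sum()),
        "F": float(y[IDX_F]),
        "released": float(y[IDX_CUM_S] + y[IDX_CUM_A] + y[IDX_CUM_SP]),
    }


def vesicle_total(y: np.ndarray) -> float:
    """Conserved vesicle count: pools + refractory-independent releases."""
    t = pool_totals(y)
    return t["R"] + t["U"] + t["V"] + t["W"] + t["released"]


def pool_rhs(y: np.ndarray, Ca_cyt: float, Ca_AZ: float,
             params: ReleaseParams) -> np.ndarray:
    """Mass-action derivatives of the full release state (42 components)."""
    out = np.empty(N_REL_STATE)
    return _release_rhs(np.asarray(y, dtype=np.float64), float(Ca_cyt),
                        float(Ca_AZ), params.as_array(), out)


def sensor_rhs(occupancy: np.ndarray, Ca_driving: float,
               params: ReleaseParams):
    """Derivatives of a 6x3 sensor occupancy grid plus its fusion rates.

    ``occupancy[m, n]`` is the vesicle mass with m Ca2+ on the synchronous
    sensor and n on the asynchronous sensor.  Returns ``(d_occupancy,
    (sync_rate, async_rate, spont_rate))``.  Pure sensor kinetics: pool
    transitions are handled by :func:`pool_rhs`.
    """
    occ = np.asarray(occupancy, dtype=np.float64)
    if occ.shape != (6, 3):
        raise ValueError("occupancy must have shape (6, 3)")
    if (occ < -1e-12).any():
        raise ValueError("negative occupancy mass")
    if Ca_driving < 0:
        raise ValueError("Ca_driving must be >= 0")
    rp = params.as_array()
    d = np.zeros((6, 3))
    rates = np.zeros(3)
    for m in range(6):
        for n in range(3):
            s_on, s_off, a_on, a_off = _sensor_rates(m, n, float(Ca_driving),
                                                     rp)
            x = occ[m, n]
            d[m, n] -= (s_on + s_off + a_on + a_off) * x
            if m < 5:
                d[m + 1, n] += s_on * x
            if m > 0:
                d[m - 1, n] += s_off * x
            if n < 2:
                d[m, n + 1] += a_on * x
            if n > 0:
                d[m, n - 1] += a_off * x
            hs, ha, hsp = _hazards(m, n, rp)
            d[m, n] -= (hs + ha + hsp) * x
            rates[0] += hs * x
            rates[1] += ha * x
            rates[2] += hsp * x
    return d, (float(rates[0]), float(rates[1]), float(rates[2]))


def fusion_hazard(m: int, n: int, params: ReleaseParams):
    """(sync, async, spont) fusion hazards of sensor state (m, n)."""
    return _hazards(m, n, params.as_array())


def apply_refractoriness(site_states: np.ndarray, fused: np.ndarray,
                         params: ReleaseParams, dt: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Advance release-site refractoriness by one step of length ``dt``.

    ``site_states``: integer array, 0 = free, 1 = occupied (primed vesicle
    present), 2 = refractory.  Sites flagged in ``fused`` become
    refractory; refractory sites recover to free with probability
    ``1 - exp(-kRF dt)`` (expected refractory dwell 1/kRF).  Refractory
    sites cannot accept newly primed vesicles.
    """
    if params.kRF <= 0:
        raise ValueError("kRF must be > 0")
    s = np.array(site_states, dtype=np.int64)
    recover = (s == 2) & (rng.random(s.shape) < -np.expm1(-params.kRF * dt))
    s[recover] = 0
    s[np.asarray(fused, dtype=bool)] = 2
    return s


def release_probability(released, initial_RRP: float) -> float:
    """P_r: vesicles released in the scoring window over the initial RRP."""
    if initial_RRP <= 0:
        raise ValueError("initial RRP must be > 0")
    return float(released) / float(initial_RRP)


def equilibrium_sensor_distribution(ca: float,
                                    params: ReleaseParams) -> np.ndarray:
    """Detailed-balance occupancy of the 6x3 sensor grid at clamped Ca.

    Fusion hazards are neglected (they are small perturbations at resting
    Ca); the S and A sensors equilibrate independently, each as a
    birth-death chain.
    """
    rp = params.as_array()

    def chain(nmax, on0, off0):
        w = np.ones(nmax + 1)
        for k in range(1, nmax + 1):
            fwd = (nmax - (k - 1)) * on0 * ca
            bwd = k * off0 * rp[i_B_COOP] ** (k - 1)
            w[k] = w[k - 1] * fwd / bwd
        return w / w.sum()

    ws = chain(5, rp[i_S_ALPHA], rp[i_S_BETA])
    wa = chain(2, rp[i_A_LAMBDA], rp[i_A_DELTA])
    return np.outer(ws, wa)


def steady_state_spontaneous_rate(Ca_cyt_rest: float,
                                  params: ReleaseParams,
                                  rrp_size: float | None = None) -> float:
    """Spontaneous fusion rate (ms^-1) of the relaxed RRP at clamped Ca_cyt.

    Sensors are taken at their clamped-Ca equilibrium; the primed-pool mass
    defaults to the fully primed N_sites.  The rate is the gamma1 hazard
    weighted by the ligand-free occupancy, and scales linearly with the
    RRP mass.
    """
    if Ca_cyt_rest < 0:
        raise ValueError("Ca_cyt_rest must be >= 0")
    rrp = float(params.N_sites) if rrp_size is None else float(rrp_size)
    occ = equilibrium_sensor_distribution(float(Ca_cyt_rest), params)
    return params.gamma1 * occ[0, 0] * rrp
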