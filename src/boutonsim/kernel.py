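"""Hybrid stochastic-deterministic integration kernel (numba).

One fixed time step advances (i) the deterministic subsystem -- compartment
Ca2+, IP3 metabolism, membrane voltage and, in deterministic-release mode,
the mass-action vesicle/sensor occupancies -- by classical RK4 with the
discrete channel states frozen, and (ii) the discrete subsystem -- IP3R and
VGCC channel states and, in stochastic-release mode, per-vesicle sensor
states and release-site occupancy -- by one step of a fixed-step jump
process.

The per-step jump probability uses the exact single-jump form
``p_exit = 1 - exp(-k_total dt)`` with branching proportional to the
individual rates.  To first order this is the textbook ``rate * dt`` rule
(and is equivalent to the Gillespie algorithm with a fixed step), but it
remains a valid probability when an open IP3R momentarily sees its own
microdomain Ca2+ of tens of uM, where exit rates exceed 1000/ms and the
literal product would overflow.

Continuous state vector (length 10, + 42 release components in
deterministic-release mode):
  [0] Ca_cyt  [1] Ca_IPRn  [2] Ca_AZ  [3] Ca_total  [4] IP3
  [5] PLC  [6] G  [7] V  [8] n  [9] h
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .calcium import _calcium_rhs, _ca_er, _ip3_rhs
from .exocytosis import (_release_rhs, _release_rates, _sensor_rates,
                         _hazards, IDX_R, IDX_U, IDX_V0, IDX_W0, IDX_F,
                         IDX_CUM_S, IDX_CUM_A, IDX_CUM_SP, N_REL_STATE)
from .ip3r import _occupancy, _rates_with_occ
from .membrane import _membrane_rhs
from .params import (i_AZ_AREA, i_N_AZ, i_CLUSTER_AREA,
                     i_KMOB, i_KDEMOB, i_KPRIMING, i_KUNPR, i_KATTACH,
                     i_KDETACH, i_KRF, i_N_SITES)
from .vgcc import _rates as _vgcc_rates
from .vgcc import _single_channel_current, _flux_from_current

N_CORE = 10

# record columns
COLUMNS = ("time_ms", "Ca_cyt_uM", "Ca_IPRn_uM", "Ca_AZ_uM", "Ca_ER_uM",
           "Ca_total_uM", "IP3_uM", "V_mV", "n_gate", "h_gate",
           "Po_IPR", "Po_VGCC",
           "rate_sync_per_ms", "rate_async_per_ms", "rate_spont_per_ms",
           "cum_sync", "cum_async", "cum_spont",
           "RRP", "U_pool", "R_pool", "F_sites")
N_COLS = len(COLUMNS)

STATUS_OK = 0
STATUS_NAN = 1

# event mode codes
MODE_SPONT, MODE_SYNC, MODE_ASYNC = 0, 1, 2


@njit(cache=True)
def _iapp(t, onsets, width, amp):
    for i in range(onsets.size):
        if onsets[i] <= t < onsets[i] + width:
            return amp
    return 0.0


@njit(cache=True)
def _cont_rhs(t, y, po_ipr, po_vgcc, iapp, cp, kp, mp, memp, vp, rp,
              n_vgcc, det_release, dy):
    is_pA = _single_channel_current(y[7], po_vgcc, vp)
    i_ca = (n_vgcc / (vp[i_AZ_AREA] * vp[i_N_AZ])) * vp[i_CLUSTER_AREA] * is_pA
    j_vgcc = _flux_from_current(i_ca, vp)
    d0, d1, d2, d3 = _calcium_rhs(y[0], y[1], y[2], y[3], y[4], po_ipr,
                                  j_vgcc, cp, kp)
    di, dplc, dg = _ip3_rhs(y[4], y[5], y[6], y[0], t, mp)
    dv, dn, dh = _membrane_rhs(y[7], y[8], y[9], iapp, y[0], i_ca, memp)
    dy[0] = d0
    dy[1] = d1
    dy[2] = d2
    dy[3] = d3
    dy[4] = di
    dy[5] = dplc
    dy[6] = dg
    dy[7] = dv
    dy[8] = dn
    dy[9] = dh
    if det_release:
        _release_rhs(y[N_CORE:], y[0], y[2], rp, dy[N_CORE:])


@njit(cache=True)
def _rk4(t, y, dt, po_ipr, po_vgcc, onsets, width, amp,
         cp, kp, mp, memp, vp, rp, n_vgcc, det_release,
         k1, k2, k3, k4, yt):
    i0 = _iapp(t, onsets, width, amp)
    i1 = _iapp(t + 0.5 * dt, onsets, width, amp)
    i2 = _iapp(t + dt, onsets, width, amp)
    _cont_rhs(t, y, po_ipr, po_vgcc, i0, cp, kp, mp, memp, vp, rp,
              n_vgcc, det_release, k1)
    for i in range(y.size):
        yt[i] = y[i] + 0.5 * dt * k1[i]
    _cont_rhs(t + 0.5 * dt, yt, po_ipr, po_vgcc, i1, cp, kp, mp, memp, vp,
              rp, n_vgcc, det_release, k2)
    for i in range(y.size):
        yt[i] = y[i] + 0.5 * dt * k2[i]
    _cont_rhs(t + 0.5 * dt, yt, po_ipr, po_vgcc, i1, cp, kp, mp, memp, vp,
              rp, n_vgcc, det_release, k3)
    for i in range(y.size):
        yt[i] = y[i] + dt * k3[i]
    _cont_rhs(t + dt, yt, po_ipr, po_vgcc, i2, cp, kp, mp, memp, vp, rp,
              n_vgcc, det_release, k4)
    for i in range(y.size):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def _jump(s, r1, r2, t1, t2, dt):
    """One DTMC step with two candidate transitions out of state s."""
    tot = r1 + r2
    if tot <= 0.0:
        return s
    p_exit = 1.0 - np.exp(-tot * dt)
    u = np.random.random()
    if u < p_exit:
        if np.random.random() * tot < r1:
            return t1
        return t2
    return s


@njit(cache=True)
def _bernoulli(rate, dt):
    if rate <= 0.0:
        return False
    return np.random.random() < 1.0 - np.exp(-rate * dt)


SITE_FREE, SITE_V, SITE_W, SITE_REFR = 0, 1, 2, 3


@njit(cache=True)
def run_hybrid(cp, kp, mp, memp, vp, rp, iprp, gate_cyt,
               n_ipr, n_vgcc, dt, n_steps,
               onsets, width, amp,
               y0, det_release,
               r0_count, u0_count, site_state0, site_m0, site_n0,
               seed, record_stride):
    """Advance the full bouton model for ``n_steps`` steps of ``dt`` ms.

    Returns ``(records, ev_times, ev_modes, n_events, status)``.  In
    deterministic-release mode the 42 release components live at the tail
    of ``y0`` and the site arguments are ignored; in stochastic-release
    mode ``y0`` has 10 components and vesicles/sites are simulated as a
    per-site jump process.
    """
    np.random.seed(seed)
    y = y0.copy()
    nvar = y.size
    k1 = np.empty(nvar)
    k2 = np.empty(nvar)
    k3 = np.empty(nvar)
    k4 = np.empty(nvar)
    yt = np.empty(nvar)

    ipr_states = np.zeros(n_ipr, dtype=np.int8)       # all start in R
    vgcc_states = np.zeros(n_vgcc, dtype=np.int8)     # all start in C1

    n_sites = int(rp[i_N_SITES])
    site_state = site_state0.copy()
    site_m = site_m0.copy()
    site_n = site_n0.copy()
    r_count = r0_count
    u_count = u0_count
    cum_s = 0
    cum_a = 0
    cum_sp = 0

    max_events = 8192
    ev_times = np.empty(max_events)
    ev_modes = np.empty(max_events, dtype=np.int8)
    n_events = 0

    n_rec = n_steps // record_stride + 1
    rec = np.zeros((n_rec, N_COLS))
    i_rec = 0

    # cached IP3 occupancy factors (IP3 varies slowly)
    KO, KA, KI = _occupancy(y[4], iprp)
    last_ip3 = y[4]

    for step in range(n_steps + 1):
        t = step * dt
        po_ipr = 0.0
        for c in range(n_ipr):
            if ipr_states[c] == 2:
                po_ipr += 1.0
        po_ipr /= n_ipr
        po_vgcc = 0.0
        if n_vgcc > 0:
            for c in range(n_vgcc):
                if vgcc_states[c] == 4:
                    po_vgcc += 1.0
            po_vgcc /= n_vgcc

        if step % record_stride == 0:
            rec[i_rec, 0] = t
            rec[i_rec, 1] = y[0]
            rec[i_rec, 2] = y[1]
            rec[i_rec, 3] = y[2]
            rec[i_rec, 4] = _ca_er(y[0], y[1], y[2], y[3], cp)
            rec[i_rec, 5] = y[3]
            rec[i_rec, 6] = y[4]
            rec[i_rec, 7] = y[7]
            rec[i_rec, 8] = y[8]
            rec[i_rec, 9] = y[9]
            rec[i_rec, 10] = po_ipr
            rec[i_rec, 11] = po_vgcc
            if det_release:
                rs, ra, rsp = _release_rates(y[N_CORE:], rp)
                rec[i_rec, 12] = rs
                rec[i_rec, 13] = ra
                rec[i_rec, 14] = rsp
                rec[i_rec, 15] = y[N_CORE + IDX_CUM_S]
                rec[i_rec, 16] = y[N_CORE + IDX_CUM_A]
                rec[i_rec, 17] = y[N_CORE + IDX_CUM_SP]
                vtot = 0.0
                wtot = 0.0
                for i in range(18):
                    vtot += y[N_CORE + IDX_V0 + i]
                    wtot += y[N_CORE + IDX_W0 + i]
                rec[i_rec, 18] = vtot + wtot
                rec[i_rec, 19] = y[N_CORE + IDX_U]
                rec[i_rec, 20] = y[N_CORE + IDX_R]
                rec[i_rec, 21] = y[N_CORE + IDX_F]
            else:
                rec[i_rec, 15] = cum_s
                rec[i_rec, 16] = cum_a
                rec[i_rec, 17] = cum_sp
                rrp = 0
                nrefr = 0
                for s in range(n_sites):
                    if site_state[s] == SITE_V or site_state[s] == SITE_W:
                        rrp += 1
                    elif site_state[s] == SITE_REFR:
                        nrefr += 1
                rec[i_rec, 18] = rrp
                rec[i_rec, 19] = u_count
                rec[i_rec, 20] = r_count
                rec[i_rec, 21] = nrefr
            i_rec += 1
            if not (np.isfinite(y[0]) and np.isfinite(y[7])):
                return rec, ev_times, ev_modes, n_events, STATUS_NAN

        if step == n_steps:
            break

        # --- deterministic subsystem ---------------------------------
        _rk4(t, y, dt, po_ipr, po_vgcc, onsets, width, amp,
             cp, kp, mp, memp, vp, rp, n_vgcc, det_release,
             k1, k2, k3, k4, yt)
        for i in range(4):          # non-negativity guard, concentrations
            if y[i] < 0.0:
                y[i] = 0.0
        if y[4] < 0.0:
            y[4] = 0.0
        if det_release:
            for i in range(N_CORE, nvar):
                if y[i] < 0.0:
                    y[i] = 0.0

        # --- IP3R channels (ligand: microdomain Ca around the cluster) ---
        if abs(y[4] - last_ip3) > 1e-9 + 1e-6 * last_ip3:
            KO, KA, KI = _occupancy(y[4], iprp)
            last_ip3 = y[4]
        ipr_lig = y[0] if gate_cyt else y[1]
        ir = _rates_with_occ(ipr_lig, KO, KA, KI, iprp)
        for c in range(n_ipr):
            s = ipr_states[c]
            if s == 0:
                ipr_states[c] = _jump(0, ir[0], ir[6], 1, 3, dt)
            elif s == 1:
                ipr_states[c] = _jump(1, ir[1], ir[2], 0, 2, dt)
            elif s == 2:
                ipr_states[c] = _jump(2, ir[3], ir[4], 1, 3, dt)
            else:
                ipr_states[c] = _jump(3, ir[5], ir[7], 2, 0, dt)

        # --- VGCC channels -------------------------------------------
        if n_vgcc > 0:
            vr = _vgcc_rates(y[7], vp)
            for c in range(n_vgcc):
                s = vgcc_states[c]
                pf = vr[s] if s < 4 else 0.0
                pb = vr[4 + s - 1] if s > 0 else 0.0
                vgcc_states[c] = _jump(s, pf, pb, s + 1, s - 1, dt)

        # --- stochastic vesicles -------------------------------------
        if not det_release:
            ca_c = y[0]
            ca_az = y[2]
            if r_count > 0 and _bernoulli(rp[i_KMOB] * ca_c * r_count, dt):
                r_count -= 1
                u_count += 1
            if u_count > 0 and _bernoulli(rp[i_KDEMOB] * u_count, dt):
                u_count -= 1
                r_count += 1
            prime_rate = rp[i_KPRIMING] * ca_c * u_count / n_sites
            for s in range(n_sites):
                st = site_state[s]
                if st == SITE_FREE:
                    if u_count > 0 and _bernoulli(prime_rate, dt):
                        site_state[s] = SITE_V
                        site_m[s] = 0
                        site_n[s] = 0
                        u_count -= 1
                        prime_rate = rp[i_KPRIMING] * ca_c * u_count / n_sites
                elif st == SITE_REFR:
                    if _bernoulli(rp[i_KRF], dt):
                        site_state[s] = SITE_FREE
                else:
                    drive = ca_c if st == SITE_V else ca_az
                    m = site_m[s]
                    n = site_n[s]
                    s_on, s_off, a_on, a_off = _sensor_rates(m, n, drive, rp)
                    hs, ha, hsp = _hazards(m, n, rp)
                    if st == SITE_V:
                        conv = rp[i_KATTACH] * ca_az
                        unpr = rp[i_KUNPR]
                    else:
                        conv = rp[i_KDETACH]
                        unpr = 0.0
                    tot = s_on + s_off + a_on + a_off + conv + unpr \
                        + hs + ha + hsp
                    if tot <= 0.0:
                        continue
                    if np.random.random() >= 1.0 - np.exp(-tot * dt):
                        continue
                    x = np.random.random() * tot
                    if x < hs:                       # synchronous fusion
                        site_state[s] = SITE_REFR
                        if n_events < max_events:
                            ev_times[n_events] = t + dt
                            ev_modes[n_events] = MODE_SYNC
                            n_events += 1
                        cum_s += 1
                        continue
                    x -= hs
                    if x < ha:                       # asynchronous fusion
                        site_state[s] = SITE_REFR
                        if n_events < max_events:
                            ev_times[n_events] = t + dt
                            ev_modes[n_events] = MODE_ASYNC
                            n_events += 1
                        cum_a += 1
                        continue
                    x -= ha
                    if x < hsp:                      # spontaneous fusion
                        site_state[s] = SITE_REFR
                        if n_events < max_events:
                            ev_times[n_events] = t + dt
                            ev_modes[n_events] = MODE_SPONT
                            n_events += 1
                        cum_sp += 1
                        continue
                    x -= hsp
                    if x < s_on:
                        site_m[s] = m + 1
                        continue
                    x -= s_on
                    if x < s_off:
                        site_m[s] = m - 1
                        continue
                    x -= s_off
                    if x < a_on:
                        site_n[s] = n + 1
                        continue
                    x -= a_on
                    if x < a_off:
                        site_n[s] = n - 1
                        continue
                    x -= a_off
                    if x < conv:
                        site_state[s] = SITE_W if st == SITE_V else SITE_V
                        continue
                    # unpriming (V only): vesicle back to U, site freed
                    site_state[s] = SITE_FREE
                    u_count += 1
                    prime_rate = rp[i_KPRIMING] * ca_c * u_count / n_sites

    return rec, ev_times, ev_modes, n_events, STATUS_OK


@njit(cache=True)
def run_release_clamp(rp, y0, ca_cyt, ca_az, dt, n_steps, record_stride):
    """Deterministic dual-sensor release under clamped Ca2+ levels.

    Integrates the 42-component release state with RK4 and returns
    ``(times, rates, pools)`` where ``rates`` has columns (sync, async,
    spont) in vesicles/ms and ``pools`` columns (RRP, U, R, F, cum_total).
    """
    y = y0.copy()
    k1 = np.empty(N_REL_STATE)
    k2 = np.empty(N_REL_STATE)
    k3 = np.empty(N_REL_STATE)
    k4 = np.empty(N_REL_STATE)
    yt = np.empty(N_REL_STATE)
    n_rec = n_steps // record_stride + 1
    times = np.empty(n_rec)
    rates = np.empty((n_rec, 3))
    pools = np.empty((n_rec, 5))
    i_rec = 0
    for step in range(n_steps + 1):
        if step % record_stride == 0:
            t = step * dt
            rs, ra, rsp = _release_rates(y, rp)
            times[i_rec] = t
            rates[i_rec, 0] = rs
            rates[i_rec, 1] = ra
            rates[i_rec, 2] = rsp
            vtot = 0.0
            wtot = 0.0
            for i in range(18):
                vtot += y[IDX_V0 + i]
                wtot += y[IDX_W0 + i]
            pools[i_rec, 0] = vtot + wtot
            pools[i_rec, 1] = y[IDX_U]
            pools[i_rec, 2] = y[IDX_R]
            pools[i_rec, 3] = y[IDX_F]
            pools[i_rec, 4] = y[IDX_CUM_S] + y[IDX_CUM_A] + y[IDX_CUM_SP]
            i_rec += 1
        if step == n_steps:
            break
        _release_rhs(y, ca_cyt, ca_az, rp, k1)
        for i in range(N_REL_STATE):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _release_rhs(yt, ca_cyt, ca_az, rp, k2)
        for i in range(N_REL_STATE):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _release_rhs(yt, ca_cyt, ca_az, rp, k3)
        for i in range(N_REL_STATE):
            yt[i] = y[i] + dt * k3[i]
        _release_rhs(yt, ca_cyt, ca_az, rp, k4)
        for i in range(N_REL_STATE):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if y[i] < 0.0:
                y[i] = 0.0
    return times, rates, pools
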