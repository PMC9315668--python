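"""Four-state IP3 receptor gating model.

The channel occupies one of four states -- Resting (R), Active (A), Open
(O), Inactive (I) -- binding 0, 2, 2 and 5 Ca2+ respectively.  Ligand
dependence enters through harmonic-mean combinations of elementary binding
steps (the ``j`` constants) and through IP3 occupancy factors KO, KA, KI
(Hill functions of IP3).  The same parameterisation, with different values
of a1, a3, j22, j23, j45 and the R<->I rates, fits single-channel records
from wild-type and 3xTg-AD cortical neurons; the AD channel is a
gain-of-function variant with a ~7-fold higher open probability at
saturating ligands.

State encoding used throughout: 0=R, 1=A, 2=O, 3=I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import (IP3RGatingParams, i_A1, i_NO, i_KOD, i_A2, i_NA, i_KAD,
                     i_A3, i_NI, i_KID, i_J01, i_J12, i_J22, i_J23, i_J45,
                     i_JT01, i_JT45)

STATE_NAMES = ("R", "A", "O", "I")
STATE_R, STATE_A, STATE_O, STATE_I = 0, 1, 2, 3
CA_BOUND = (0, 2, 2, 5)
OPEN_STATE = STATE_O


@njit(cache=True)
def _hill(x, a, n, K):
    if x <= 0.0:
        return 0.0
    xn = x ** n
    if not np.isfinite(xn):       # overflow at extreme ligand * exponent
        return a
    return a * xn / (xn + K ** n)


@njit(cache=True)
def _occupancy(ip3, p):
    KO = _hill(ip3, p[i_A1], p[i_NO], p[i_KOD])
    KA = _hill(ip3, p[i_A2], p[i_NA], p[i_KAD])
    KI = _hill(ip3, p[i_A3], p[i_NI], p[i_KID])
    return KO, KA, KI


@njit(cache=True)
def _rates_with_occ(ca, KO, KA, KI, p):
    """Eight transition rates (kRA,kAR,kAO,kOA,kOI,kIO,kRI,kIR) in ms^-1,
    with the IP3 occupancy factors supplied by the caller (they depend on
    IP3 only, which varies slowly in the coupled model)."""
    if ca <= 0.0:
        # with no Ca2+ the channel cannot leave R; the zero-Ca limit is
        # fully absorbing in R.
        return np.zeros(8)
    c2 = ca * ca
    c3 = c2 * ca
    c5 = c2 * c3
    hRA = 1.0 / (p[i_J01] * ca) + 1.0 / (p[i_J12] * c2)
    hOI = 1.0 / (p[i_J23] * c3) + 1.0 / (p[i_J45] * c5)
    hRI = 1.0 / (p[i_JT01] * ca) + 1.0 / (p[i_JT45] * c5)
    out = np.empty(8)
    out[0] = 1.0 / hRA                                   # kRA
    out[1] = 1.0 / (KA * c2 * hRA) if KA > 0 else 0.0    # kAR
    out[2] = p[i_J22] / KA if KA > 0 else 0.0            # kAO
    out[3] = p[i_J22] / KO if KO > 0 else 0.0            # kOA
    out[4] = 1.0 / (KO * c2 * hOI) if KO > 0 else 0.0    # kOI
    out[5] = 1.0 / (KI * c5 * hOI) if KI > 0 else 0.0    # kIO
    out[6] = 1.0 / hRI                                   # kRI
    out[7] = 1.0 / (KI * c5 * hRI) if KI > 0 else 0.0    # kIR
    return out


@njit(cache=True)
def _rates(ca, ip3, p):
    """Eight transition rates (kRA,kAR,kAO,kOA,kOI,kIO,kRI,kIR) in ms^-1."""
    KO, KA, KI = _occupancy(ip3, p)
    return _rates_with_occ(ca, KO, KA, KI, p)


@dataclass
class OccupancyFactors:
    KO: float
    KA: float
    KI: float


@dataclass
class IP3RRates:
    kRA: float
    kAR: float
    kAO: float
    kOA: float
    kOI: float
    kIO: float
    kRI: float
    kIR: float

    def as_array(self) -> np.ndarray:
        return np.array([self.kRA, self.kAR, self.kAO, self.kOA,
                         self.kOI, self.kIO, self.kRI, self.kIR])


def occupancy_factors(ip3: float, params: IP3RGatingParams) -> OccupancyFactors:
    """IP3 occupancy factors (Hill saturations) KO, KA, KI.

    KO and KA carry uM^-2 units (two bound Ca2+), KI uM^-5 (five bound);
    each saturates at its amplitude a1, a2, a3 as IP3 grows.
    """
    if ip3 < 0:
        raise ValueError(f"ip3 must be >= 0, got {ip3}")
    KO, KA, KI = _occupancy(float(ip3), params.as_array())
    return OccupancyFactors(KO, KA, KI)


def transition_rates(ca: float, ip3: float,
                     params: IP3RGatingParams) -> IP3RRates:
    """Transition rates of the R<->A<->O<->I<->R chain at given ligands.

    ``ca`` is the Ca2+ concentration in the microdomain around the cluster
    (uM); ``ip3`` in uM.  ca = 0 is handled as the limit in which every
    rate vanishes (the channel is absorbed in R).
    """
    if ca < 0:
        raise ValueError(f"ca must be >= 0, got {ca}")
    if ip3 < 0:
        raise ValueError(f"ip3 must be >= 0, got {ip3}")
    return IP3RRates(*_rates(float(ca), float(ip3), params.as_array()))


def generator_matrix(ca: float, ip3: float,
                     params: IP3RGatingParams) -> np.ndarray:
    """4x4 CTMC generator Q (rows sum to zero; order R, A, O, I)."""
    r = transition_rates(ca, ip3, params)
    Q = np.array([
        [-(r.kRA + r.kRI), r.kRA, 0.0, r.kRI],
        [r.kAR, -(r.kAR + r.kAO), r.kAO, 0.0],
        [0.0, r.kOA, -(r.kOA + r.kOI), r.kOI],
        [r.kIR, 0.0, r.kIO, -(r.kIO + r.kIR)],
    ])
    return Q


def stationary_distribution(ca: float, ip3: float,
                            params: IP3RGatingParams) -> np.ndarray:
    """Stationary distribution pi of the four-state chain.

    Solves pi Q = 0, sum(pi) = 1 by least squares on the augmented system.
    Raises ``ValueError`` for degenerate ligand combinations that make the
    chain reducible (e.g. ca = 0).
    """
    if ca <= 0 or ip3 <= 0:
        raise ValueError("stationary distribution requires ca > 0 and ip3 > 0")
    Q = generator_matrix(ca, ip3, params)
    if not np.all(np.isfinite(Q)) or np.allclose(Q, 0.0):
        raise ValueError("singular rate matrix at the given ligands")
    M = np.vstack([Q.T, np.ones(4)])
    b = np.zeros(5)
    b[4] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    if s <= 0 or not np.isfinite(s):
        raise ValueError("singular rate matrix at the given ligands")
    return pi / s


def stationary_open_probability(ca: float, ip3: float,
                                params: IP3RGatingParams) -> float:
    """Analytic stationary open probability P_o at clamped ligands."""
    return float(stationary_distribution(ca, ip3, params)[STATE_O])


@dataclass
class ChannelTrajectory:
    """Time-stamped discrete state path of one channel (or a cluster)."""

    times: np.ndarray          # ms, uniform grid of length n_steps + 1
    states: np.ndarray         # int8, shape (n_steps + 1,) or (n, n_channels)
    dt: float                  # ms
    open_state: int = STATE_O

    @property
    def open_fraction_trace(self) -> np.ndarray:
        s = self.states
        if s.ndim == 1:
            return (s == self.open_state).astype(np.float64)
        return (s == self.open_state).mean(axis=1)


@njit(cache=True)
def _simulate_path(ca_trace, ip3_trace, p, dt, n_steps, seed, init_state):
    np.random.seed(seed)
    states = np.empty(n_steps + 1, dtype=np.int8)
    states[0] = init_state
    s = init_state
    last_ip3 = ip3_trace[0]
    KO, KA, KI = _occupancy(last_ip3, p)
    last_ca = ca_trace[0]
    r = _rates_with_occ(last_ca, KO, KA, KI, p)
    for i in range(n_steps):
        ca = ca_trace[min(i, len(ca_trace) - 1)]
        ip3 = ip3_trace[min(i, len(ip3_trace) - 1)]
        if ip3 != last_ip3:
            KO, KA, KI = _occupancy(ip3, p)
            last_ip3 = ip3
            last_ca = np.nan
        if ca != last_ca:
            r = _rates_with_occ(ca, KO, KA, KI, p)
            last_ca = ca
        if s == 0:        # R -> A or R -> I
            p1, p2, t1, t2 = r[0] * dt, r[6] * dt, 1, 3
        elif s == 1:      # A -> R or A -> O
            p1, p2, t1, t2 = r[1] * dt, r[2] * dt, 0, 2
        elif s == 2:      # O -> A or O -> I
            p1, p2, t1, t2 = r[3] * dt, r[4] * dt, 1, 3
        else:             # I -> O or I -> R
            p1, p2, t1, t2 = r[5] * dt, r[7] * dt, 2, 0
        if p1 + p2 >= 1.0:
            # flag overflow by returning an invalid state marker
            states[i + 1 :] = -1
            return states
        u = np.random.random()
        if u < p1:
            s = t1
        elif u < p1 + p2:
            s = t2
        states[i + 1] = s
    return states


def simulate_channel(ca_trace, ip3_trace, dt: float, T: float, seed: int,
                     params: IP3RGatingParams,
                     init_state: int = STATE_R) -> ChannelTrajectory:
    """Fixed-step DTMC simulation of a single IP3R channel.

    ``ca_trace``/``ip3_trace`` may be scalars (clamped ligands) or arrays
    sampled on the dt grid.  Per-step transition probability is rate*dt
    with at most one transition per step; the step must satisfy
    (total exit rate)*dt < 0.1, otherwise a ``ValueError`` suggests a
    smaller dt.  Identical seeds give identical trajectories.
    """
    n_steps = int(round(T / dt))
    ca = np.atleast_1d(np.asarray(ca_trace, dtype=np.float64))
    ip3 = np.atleast_1d(np.asarray(ip3_trace, dtype=np.float64))
    p = params.as_array()
    # a-priori dt check on the ligand envelope
    worst = 0.0
    for c in (ca.min(), ca.max()):
        for q in (ip3.min(), ip3.max()):
            r = _rates(float(c), float(q), p)
            worst = max(worst,
                        r[0] + r[6], r[1] + r[2], r[3] + r[4], r[5] + r[7])
    if worst * dt >= 0.1:
        raise ValueError(
            f"max total exit rate {worst:.3g}/ms times dt={dt} ms exceeds "
            f"0.1; use dt < {0.1 / worst:.3g} ms")
    states = _simulate_path(ca, ip3, p, dt, n_steps, np.uint32(seed),
                            init_state)
    if states[-1] < 0:
        raise ValueError("transition probability overflow during simulation; "
                         "reduce dt")
    times = np.arange(n_steps + 1) * dt
    return ChannelTrajectory(times=times, states=states, dt=dt)


@dataclass
class DwellTimeStats:
    tau_open: float            # ms, mean contiguous open sojourn
    tau_closed: float          # ms, mean contiguous closed sojourn
    p_open_empirical: float    # fraction of time spent open
    n_openings: int


def dwell_time_stats(traj: ChannelTrajectory) -> DwellTimeStats:
    """Mean open/closed dwell times and empirical open probability.

    Sojourns are measured between state changes on the dt grid; the first
    and last (censored) sojourns are discarded.  Raises ``ValueError`` if
    the trajectory contains no opening.
    """
    is_open = traj.states == traj.open_state
    if is_open.all():
        return DwellTimeStats(float(len(is_open)) * traj.dt, np.nan, 1.0, 1)
    if not is_open.any():
        raise ValueError("trajectory contains no openings: dwell-time "
                         "statistics undefined")
    # run-length encode the open/closed indicator
    change = np.flatnonzero(np.diff(is_open.astype(np.int8)) != 0) + 1
    bounds = np.concatenate([[0], change, [len(is_open)]])
    lengths = np.diff(bounds) * traj.dt
    opens = is_open[bounds[:-1]]
    # censor first and last sojourns
    lengths, opens = lengths[1:-1], opens[1:-1]
    tau_o = float(lengths[opens].mean()) if opens.any() else np.nan
    tau_c = float(lengths[~opens].mean()) if (~opens).any() else np.nan
    return DwellTimeStats(tau_o, tau_c, float(is_open.mean()),
                          int(opens.sum()))


def cluster_open_fraction(states) -> float:
    """Fraction of channels of a cluster in the open state (Nopen/N)."""
    s = np.asarray(states)
    if s.size < 1:
        raise ValueError("empty cluster")
    return float(np.mean(s == STATE_O))


def po_surface(ca_grid, ip3_grid, params: IP3RGatingParams) -> np.ndarray:
    """Stationary P_o on a (ca, ip3) grid; shape (len(ca), len(ip3))."""
    out = np.empty((len(ca_grid), len(ip3_grid)))
    for i, c in enumerate(ca_grid):
        for j, q in enumerate(ip3_grid):
            out[i, j] = stationary_open_probability(float(c), float(q), params)
    return out
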