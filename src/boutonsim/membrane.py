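"""Hodgkin-Huxley-style membrane voltage of the bouton and stimulus protocols.

Current balance:  Cm dV/dt = Iapp + INa + IK + ICl + ICa-term, with

    INa = -(gNa m_inf^3 h)(V - ENa) - gNaleak (V - ENa)
    IK  = -(gK n^4 + gAHP Ca/(1 + Ca))(V - EK) - gKleak (V - EK)
    ICl = -gClleak (V - ECl)

The Na+ activation gate is instantaneous (m = m_inf(V)); n and h relax
with rates scaled by the temperature factor phi.  The Ca2+ current of the
VGCC cluster enters as a depolarising -ICa/Area term (inward current is
negative by convention); at ~1e-2 uA/cm^2 it is a small perturbation of
the voltage but is included for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import (MembraneParams, i_CM, i_GNA, i_GK, i_GNALEAK, i_GKLEAK,
                     i_GCLLEAK, i_PHI, i_GAHP, i_ENA, i_EK, i_ECL, i_AREA_CM2)


@njit(cache=True)
def _expm1_ratio(x):
    """x / (1 - exp(-x)) with the removable singularity at x = 0."""
    if abs(x) < 1e-7:
        return 1.0 + 0.5 * x
    return x / (1.0 - np.exp(-x))


@njit(cache=True)
def _gating_rates(v):
    """(alpha_n, beta_n, alpha_h, beta_h, alpha_m, beta_m) at V (mV)."""
    an = 0.1 * _expm1_ratio((v + 34.0) / 10.0)      # 0.01(V+34)/(1-e^-(V+34)/10)
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    ah = 0.07 * np.exp(-(v + 44.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 14.0) / 10.0))
    am = 1.0 * _expm1_ratio((v + 30.0) / 10.0)      # 0.1(V+30)/(1-e^-(V+30)/10)
    bm = 4.0 * np.exp(-(v + 55.0) / 18.0)
    return an, bn, ah, bh, am, bm


def gating_rates(V: float):
    """HH gating rates with analytic limits at the removable singularities."""
    if not np.isfinite(V):
        raise ValueError(f"V must be finite, got {V}")
    return _gating_rates(float(V))


@njit(cache=True)
def _m_inf(v):
    an, bn, ah, bh, am, bm = _gating_rates(v)
    return am / (am + bm)


def m_inf(V: float) -> float:
    """Instantaneous Na+ activation gate m_inf(V)."""
    return float(_m_inf(float(V)))


@njit(cache=True)
def _membrane_rhs(v, n, h, iapp, ca_cyt, i_ca_pA, p):
    """(dV/dt, dn/dt, dh/dt); V in mV, time in ms, Iapp in uA/cm^2."""
    an, bn, ah, bh, am, bm = _gating_rates(v)
    m = am / (am + bm)
    ina = -(p[i_GNA] * m * m * m * h) * (v - p[i_ENA]) \
        - p[i_GNALEAK] * (v - p[i_ENA])
    ahp = p[i_GAHP] * ca_cyt / (1.0 + ca_cyt)
    ik = -(p[i_GK] * n ** 4 + ahp) * (v - p[i_EK]) \
        - p[i_GKLEAK] * (v - p[i_EK])
    icl = -p[i_GCLLEAK] * (v - p[i_ECL])
    # inward (negative) Ca current depolarises: -I_Ca/Area, pA -> uA/cm^2
    ica_term = -i_ca_pA * 1e-6 / p[i_AREA_CM2]
    dv = (iapp + ina + ik + icl + ica_term) / p[i_CM]
    dn = p[i_PHI] * (an * (1.0 - n) - bn * n)
    dh = p[i_PHI] * (ah * (1.0 - h) - bh * h)
    return dv, dn, dh


@dataclass
class MembraneState:
    V: float = -58.0
    n: float = 0.06
    h: float = 0.98


def membrane_rhs(state: MembraneState, Iapp: float, Ca_cyt: float,
                 I_Ca: float, params: MembraneParams):
    """Time derivatives (dV/dt, dn/dt, dh/dt) of the membrane state.

    ``I_Ca`` is the whole-cluster Ca2+ current in pA (inward negative),
    ``Iapp`` the applied stimulus in uA/cm^2.
    """
    return _membrane_rhs(state.V, state.n, state.h, Iapp, Ca_cyt, I_Ca,
                         params.as_array())


@njit(cache=True)
def _relax(p, ca_cyt, T, dt):
    v, n, h = -60.0, 0.05, 0.9
    for _ in range(int(T / dt)):
        dv, dn, dh = _membrane_rhs(v, n, h, 0.0, ca_cyt, 0.0, p)
        v += dt * dv
        n += dt * dn
        h += dt * dh
    return v, n, h


def resting_state(params: MembraneParams, Ca_cyt: float = 0.1,
                  T: float = 200.0, dt: float = 0.01) -> MembraneState:
    """Relax the unstimulated membrane to its resting fixed point."""
    v, n, h = _relax(params.as_array(), Ca_cyt, T, dt)
    return MembraneState(V=v, n=n, h=h)


@dataclass
class StimulusProtocol:
    """Current-pulse stimulation: onsets, width and amplitude.

    Default pulse: rectangular, 1 ms wide, 20 uA/cm^2 (suprathreshold for
    the default membrane).  The paired protocol uses a 40 ms interval; the
    train protocol 20 pulses at 20 Hz (50 ms spacing).
    """

    onsets_ms: np.ndarray = field(
        default_factory=lambda: np.array([50.0]))
    width_ms: float = 1.0
    amplitude: float = 20.0        # uA/cm^2
    kind: str = "single"

    def current(self, t: float) -> float:
        for t0 in self.onsets_ms:
            if t0 <= t < t0 + self.width_ms:
                return self.amplitude
        return 0.0

    @property
    def n_pulses(self) -> int:
        return len(self.onsets_ms)


def make_protocol(kind: str = "single", *, t0: float = 50.0,
                  interval: float | None = None, n_pulses: int | None = None,
                  amplitude: float = 20.0, width: float = 1.0
                  ) -> StimulusProtocol:
    """Build one of the three stimulation protocols.

    single -> one pulse at ``t0``; paired -> two pulses 40 ms apart (or the
    given ``interval``); train -> 20 pulses at 20 Hz (50 ms spacing) unless
    ``n_pulses``/``interval`` override the defaults.
    """
    if kind == "single":
        onsets = np.array([t0])
    elif kind == "paired":
        iv = 40.0 if interval is None else float(interval)
        if iv <= 0:
            raise ValueError(f"interval must be > 0, got {iv}")
        onsets = np.array([t0, t0 + iv])
    elif kind == "train":
        iv = 50.0 if interval is None else float(interval)
        if iv <= 0:
            raise ValueError(f"interval must be > 0, got {iv}")
        n = 20 if n_pulses is None else int(n_pulses)
        onsets = t0 + iv * np.arange(n)
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    return StimulusProtocol(onsets_ms=onsets, width_ms=width,
                            amplitude=amplitude, kind=kind)


def detect_action_potentials(times: np.ndarray, v: np.ndarray,
                             threshold: float = 0.0) -> np.ndarray:
    """AP times as upward crossings of ``threshold`` (linear interpolation)."""
    v = np.asarray(v)
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return np.empty(0)
    t0, t1 = times[idx], times[idx + 1]
    v0, v1 = v[idx], v[idx + 1]
    frac = (threshold - v0) / (v1 - v0)
    return t0 + frac * (t1 - t0)
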