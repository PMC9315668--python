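"""Model parameters: presets, validation, serialization.

Every quantity printed in the source tables is transcribed here with units
normalised to the package's internal system (ms, uM, mV, pS, L).  Two tags
select a preset:

* ``condition`` -- ``"WT"`` (wild-type) or ``"AD"`` (familial Alzheimer's
  disease, 3xTg-AD fitted IP3R gating plus altered IP3 metabolism).
* ``coupling`` -- ``"NC"`` (normal ER-active-zone coupling) or ``"HC"``
  (high coupling, standing in for down-regulated Ca2+ buffering proteins).

Rate constants printed as "us^-1" in the IP3-metabolism table are stored as
s^-1 converted to ms^-1: taken literally as microseconds they would give a
sub-microsecond IP3 turnover, whereas the conversion used here yields
tau_IP3 = 1/(k3k + k5p) ~ 0.66 s, the timescale expected of a slow second
messenger.  The choice is recorded in exported metadata.

Each dataclass exposes ``as_array()`` producing the flat float64 vector
consumed by the numba kernels; the ``i_*`` module constants name the slots.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

FARADAY = 96485.33212  # C/mol

# ---------------------------------------------------------------------------
# Calcium compartment parameters
# ---------------------------------------------------------------------------

(i_JLEAK_IN, i_VLEAK_IN, i_K_IPR_DIFF, i_K_VGCC_DIFF, i_K_ER_LEAK, i_K_IPR,
 i_V_PMCA, i_K_PMCA, i_N_P, i_V_SERCA, i_K_SERCA, i_N_S,
 i_D1, i_D2, i_D3) = range(15)
N_CA_PARAMS = 15


@dataclass
class CalciumParams:
    """Fluxes and geometry of the four-compartment Ca2+ model."""

    Jleak_in: float = 0.03115      # uM/ms, plasma-membrane leak influx
    Vleak_in: float = 0.2          # 1/ms, R/SOCC flux coefficient (x IP3)
    k_IPR_diff: float = 10.0       # 1/ms, IP3R microdomain -> cytosol
    k_VGCC_diff: float = 0.071     # 1/ms, AZ microdomain -> cytosol
    k_ER_leak: float = 0.0022      # 1/ms, passive ER leak
    k_IPR: float = 5.0             # 1/ms, IP3R flux coefficient
    N_IPR: int = 10                # channels per IP3R cluster
    V_PMCA: float = 3.195          # uM/ms
    K_PMCA: float = 0.5            # uM
    n_P: float = 2.0               # PMCA Hill exponent
    V_SERCA: float = 10.0          # uM/ms
    K_SERCA: float = 0.26          # uM
    n_S: float = 1.75              # SERCA Hill exponent
    delta1: float = 100.0          # cytosol : IP3R-microdomain volume ratio
    delta2: float = 10.0           # cytosol : ER volume ratio
    delta3: float = 60.0           # cytosol : AZ-microdomain volume ratio
    # resting concentrations (initial conditions)
    Ca_cyt0: float = 0.1           # uM
    Ca_AZ0: float = 0.05           # uM
    Ca_total0: float = 56.0        # uM
    IP3_0: float = 0.1             # uM
    Ca_ext: float = 2000.0         # uM (2 mM)

    def as_array(self) -> np.ndarray:
        return np.array([
            self.Jleak_in, self.Vleak_in, self.k_IPR_diff, self.k_VGCC_diff,
            self.k_ER_leak, self.k_IPR, self.V_PMCA, self.K_PMCA, self.n_P,
            self.V_SERCA, self.K_SERCA, self.n_S,
            self.delta1, self.delta2, self.delta3,
        ])


# ---------------------------------------------------------------------------
# ER-AZ coupling flux
# ---------------------------------------------------------------------------

(i_VC, i_KBAR, i_KC, i_COUP_PRINTED) = range(4)
N_COUP_PARAMS = 4


@dataclass
class CouplingParams:
    """Bidirectional Ca2+ transfer between the AZ and IP3R microdomains.

    ``kbar`` is stored dimensionless: it multiplies a squared concentration
    inside the transfer flux.  ``printed_denominator`` selects the literal
    difference form ``Ca_AZ^2 - Kc^2`` (which has a pole at Ca_AZ = Kc)
    instead of the default saturating form ``Ca_AZ^2 + Kc^2``.
    """

    Vc: float = 118.0              # uM/ms, max AZ -> IP3R-microdomain flux
    kbar: float = 5.0              # dimensionless concentrating factor
    Kc: float = 20.0               # uM, half-maximal transfer constant
    preset: str = "NC"
    printed_denominator: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.Vc, self.kbar, self.Kc,
                         1.0 if self.printed_denominator else 0.0])


COUPLING_PRESETS = {
    "NC": dict(Vc=118.0, kbar=5.0, Kc=20.0),
    "HC": dict(Vc=118.0, kbar=15.0, Kc=10.0),
}

# ---------------------------------------------------------------------------
# IP3 metabolism (PLC-delta production, 3-kinase/5-phosphatase degradation,
# G-protein cascade, optional amyloid-beta drive)
# ---------------------------------------------------------------------------

(i_V0, i_VQ, i_KQ, i_K_IP3K, i_K_PLC, i_K3K, i_K5P,
 i_KF_PLC, i_KB_PLC, i_PLC_TOT, i_KF_G, i_KB_G, i_DELTA_G, i_VR, i_KR,
 i_G_TOT, i_ABETA, i_ABETA_R, i_ABETA_T1) = range(19)
N_IP3M_PARAMS = 19

_US_AS_S = 1e-3  # table rows printed "us^-1", interpreted s^-1 -> ms^-1


@dataclass
class IP3MetabolismParams:
    V0: float = 0.15               # uM, basal PLC-mediated IP3 production
    VQ: float = 7.82               # uM, amyloid-beta influence on IP3
    KQ: float = 0.0086             # ug/mL
    K_IP3k: float = 0.6            # uM, 3-kinase half-activation
    K_PLC: float = 0.01            # uM, PLC sensitivity to Ca2+
    k3k: float = 1.5 * _US_AS_S    # 1/ms, IP3 phosphorylation
    k5p: float = 0.01 * _US_AS_S   # 1/ms, IP3 dephosphorylation
    kf_PLC: float = 0.35 * _US_AS_S  # 1/ms
    kb_PLC: float = 22.0 * _US_AS_S  # 1/ms
    PLC_tot: float = 1.0           # scaled
    kf_G: float = 0.33 * _US_AS_S  # 1/ms
    kb_G: float = 2.17 * _US_AS_S  # 1/ms
    delta_G: float = 0.01          # intrinsic G-protein activity
    VR: float = 7.4                # maximal G-protein activation
    KR: float = 4467.0             # ug/mL, Abeta half-activation
    G_tot: float = 1.0             # scaled
    Abeta: float = 0.0             # ug/mL, transient amplitude (off by default)
    Abeta_r: float = 0.001         # 1/ms, decay rate of the Abeta transient
    Abeta_t1: float = 0.0          # ms, onset time
    rate_unit_scale: str = "printed us^-1 interpreted as s^-1"

    def as_array(self) -> np.ndarray:
        return np.array([
            self.V0, self.VQ, self.KQ, self.K_IP3k, self.K_PLC,
            self.k3k, self.k5p, self.kf_PLC, self.kb_PLC, self.PLC_tot,
            self.kf_G, self.kb_G, self.delta_G, self.VR, self.KR, self.G_tot,
            self.Abeta, self.Abeta_r, self.Abeta_t1,
        ])


IP3_METABOLISM_PRESETS = {
    "WT": dict(V0=0.15, VQ=7.82, KQ=0.0086, K_IP3k=0.6, K_PLC=0.01,
               k3k=1.5e-3, k5p=0.01e-3, kf_PLC=0.35e-3, kb_PLC=22.0e-3,
               kf_G=0.33e-3, kb_G=2.17e-3, delta_G=0.01, VR=7.4, KR=4467.0),
    "AD": dict(V0=0.19, VQ=380.0, KQ=0.0086, K_IP3k=1.6, K_PLC=0.016,
               k3k=0.7e-3, k5p=0.005e-3, kf_PLC=0.75e-3, kb_PLC=200.0e-3,
               kf_G=0.047e-3, kb_G=4.7e-3, delta_G=0.012, VR=10.0, KR=2000.0),
}

# ---------------------------------------------------------------------------
# IP3R gating (four-state R/A/O/I chain)
# ---------------------------------------------------------------------------

(i_A1, i_NO, i_KOD, i_A2, i_NA, i_KAD, i_A3, i_NI, i_KID,
 i_J01, i_J12, i_J22, i_J23, i_J45, i_JT01, i_JT45) = range(16)
N_IPR_PARAMS = 16


@dataclass
class IP3RGatingParams:
    """Ligand-dependent transition-rate parameters of the four-state IP3R.

    The inactivation occupancy KI uses the ``a3`` prefactor: ``a3`` is the
    only occupancy amplitude that differs between WT and AD and carries the
    uM^-5 units matching the five bound Ca2+ of the inactive state.
    """

    a1: float = 17.05043           # uM^-2
    nO: float = 2.473407
    KOd: float = 0.909078          # uM
    a2: float = 18.49186           # uM^-2
    nA: float = 0.093452
    KAd: float = 1.955650          # uM
    a3: float = 2.340259e2         # uM^-5
    nI: float = 56.84823
    KId: float = 0.089938          # uM
    j01: float = 3.031635e2        # uM^-1 ms^-1
    j12: float = 3.230063e2        # uM^-2 ms^-1
    j22: float = 4.814111          # uM^-2 ms^-1
    j23: float = 5.356155          # uM^-3 ms^-1
    j45: float = 5.625616          # uM^-5 ms^-1
    jt01: float = 3.013284e2       # uM^-1 ms^-1
    jt45: float = 2.648741         # uM^-5 ms^-1
    condition: str = "WT"
    # ligand driving channel gating in the coupled simulation: "cytosol"
    # (bulk Ca_cyt; default) or "microdomain" (Ca_IPRn, the channel's own
    # self-generated domain, which quenches every opening within
    # microseconds -- see the methods note).
    gating_ligand: str = "cytosol"

    def as_array(self) -> np.ndarray:
        return np.array([
            self.a1, self.nO, self.KOd, self.a2, self.nA, self.KAd,
            self.a3, self.nI, self.KId,
            self.j01, self.j12, self.j22, self.j23, self.j45,
            self.jt01, self.jt45,
        ])


IP3R_PRESETS = {
    "WT": dict(a1=17.05043, a3=2.340259e2, j22=4.814111, j23=5.356155,
               j45=5.625616, jt45=2.648741),
    "AD": dict(a1=1.108278e2, a3=1.4041556e2, j22=5.3978052, j23=2.0652269e3,
               j45=5.4319289, jt45=8.512829e-8),
}

# ---------------------------------------------------------------------------
# VGCC (Cav2.1 five-state chain) and flux geometry
# ---------------------------------------------------------------------------

(i_AL1, i_AL2, i_AL3, i_AL4, i_BE1, i_BE2, i_BE3, i_BE4,
 i_KV1, i_KV2, i_KV3, i_KV4,
 i_G_VGCC, i_E_CA, i_CLUSTER_AREA, i_AZ_AREA, i_N_AZ, i_V_EFF,
 i_Z_CA, i_FARADAY) = range(20)
N_VGCC_PARAMS = 20


@dataclass
class VGCCParams:
    """Cav2.1 (P/Q-type) gating rates and single-channel current geometry.

    Activation rates follow alpha_i(V) = alpha_i0 * exp(V/k_i); deactivation
    rates use beta_i(V) = beta_i0 * exp(-V/k_i) so that the channel is a
    high-threshold one (essentially shut at rest, activated by the AP).
    ``g`` and ``E_Ca`` are calibration parameters (typical Cav2.1 modelling
    values) exposed in the configuration.
    """

    alpha0: tuple = (4.04, 6.70, 4.39, 17.33)   # ms^-1 at 0 mV
    beta0: tuple = (2.88, 6.30, 8.16, 1.84)     # ms^-1 at 0 mV
    kv: tuple = (49.14, 42.08, 55.31, 26.55)    # mV slope factors
    g: float = 2.7                 # pS single-channel conductance
    E_Ca: float = 50.0             # mV
    N_VGCC: int = 35               # channels per active zone
    cluster_area: float = 0.001963  # um^2 (25 nm radius cluster)
    AZ_area: float = 0.04          # um^2
    N_AZ: float = 1.3
    V_eff: float = 2.0e-17         # L; effective flux-conversion volume (calibrated)
    z: float = 2.0
    F: float = FARADAY

    def as_array(self) -> np.ndarray:
        return np.array([
            *self.alpha0, *self.beta0, *self.kv,
            self.g, self.E_Ca, self.cluster_area, self.AZ_area, self.N_AZ,
            self.V_eff, self.z, self.F,
        ])


# ---------------------------------------------------------------------------
# Membrane excitability
# ---------------------------------------------------------------------------

(i_CM, i_GNA, i_GK, i_GNALEAK, i_GKLEAK, i_GCLLEAK, i_PHI, i_GAHP,
 i_ENA, i_EK, i_ECL, i_AREA_CM2) = range(12)
N_MEM_PARAMS = 12

# surface of a sphere with the bouton volume 0.122 um^3, in cm^2
_BOUTON_AREA_CM2 = 4.0 * math.pi * (3.0 * 0.122 / (4.0 * math.pi)) ** (2.0 / 3.0) * 1e-8


@dataclass
class MembraneParams:
    Cm: float = 1.0                # uF/cm^2
    gNa: float = 120.0             # mS/cm^2
    gK: float = 36.0               # mS/cm^2
    gNaleak: float = 0.0175        # mS/cm^2
    gKleak: float = 0.05           # mS/cm^2
    gClleak: float = 0.05          # mS/cm^2
    phi: float = 5.0               # gating temperature factor
    gAHP: float = 0.01             # mS/cm^2, Ca2+-dependent AHP conductance
    E_Na: float = 55.0             # mV
    E_K: float = -90.0             # mV
    E_Cl: float = -70.0            # mV
    area_cm2: float = _BOUTON_AREA_CM2  # membrane area for the ICa/Area term

    def as_array(self) -> np.ndarray:
        return np.array([
            self.Cm, self.gNa, self.gK, self.gNaleak, self.gKleak,
            self.gClleak, self.phi, self.gAHP,
            self.E_Na, self.E_K, self.E_Cl, self.area_cm2,
        ])


# ---------------------------------------------------------------------------
# Exocytosis (vesicle pools, dual Ca2+ sensors, refractoriness)
# ---------------------------------------------------------------------------

(i_KMOB, i_KDEMOB, i_KPRIMING, i_KUNPR, i_KATTACH, i_KDETACH, i_KRF,
 i_S_ALPHA, i_S_BETA, i_A_LAMBDA, i_A_DELTA,
 i_GAMMA1, i_GAMMA2, i_A_RATIO, i_B_COOP,
 i_N_SITES, i_N_RESERVE) = range(17)
N_REL_PARAMS = 17


@dataclass
class ReleaseParams:
    """Vesicle cycle and dual-sensor fusion parameters.

    The asynchronous fusion rate is always ``gamma3 = a * gamma2``.  Pool
    sizes are not printed in the source tables; the defaults (8 release
    sites, fully primed, 100 reserve vesicles) put the resting spontaneous
    fusion rate at ~7e-5 /ms, inside the experimentally reported
    1e-5 - 1e-4 /ms window for hippocampal boutons.
    """

    kmob: float = 5.0e-5           # uM^-1 ms^-1, reserve -> docked
    kdemob: float = 0.0022         # ms^-1
    kpriming: float = 0.027990     # uM^-1 ms^-1, docked -> primed (SRP)
    kunpr: float = 0.005356        # ms^-1
    kattach: float = 0.0015        # uM^-1 ms^-1, SRP -> channel-attached (FRP)
    kdetach: float = 0.001158      # ms^-1
    kRF: float = 0.01              # ms^-1, release-site refractory recovery
    alpha: float = 0.061200        # uM^-1 ms^-1, synchronous sensor on-rate
    beta: float = 2.32             # ms^-1, synchronous sensor off-rate
    lam: float = 0.002933          # uM^-1 ms^-1, asynchronous sensor on-rate
    delta: float = 0.014829        # ms^-1, asynchronous sensor off-rate
    gamma1: float = 9.0e-6         # ms^-1, spontaneous fusion
    gamma2: float = 2.000008       # ms^-1, synchronous fusion
    a: float = 0.025007            # gamma3 = a * gamma2
    b: float = 0.250007            # cooperativity factor (0 < b <= 1)
    N_sites: int = 8               # release sites (V + W + refractory <= N)
    N_reserve: int = 100           # initial reserve-pool size

    @property
    def gamma3(self) -> float:
        return self.a * self.gamma2

    def as_array(self) -> np.ndarray:
        return np.array([
            self.kmob, self.kdemob, self.kpriming, self.kunpr,
            self.kattach, self.kdetach, self.kRF,
            self.alpha, self.beta, self.lam, self.delta,
            self.gamma1, self.gamma2, self.a, self.b,
            float(self.N_sites), float(self.N_reserve),
        ])


# ---------------------------------------------------------------------------
# Aggregate parameter set
# ---------------------------------------------------------------------------

_GROUPS = ("calcium", "coupling", "ip3_metabolism", "ip3r", "vgcc",
           "membrane", "release")


@dataclass
class ParameterSet:
    """Fully resolved parameter set for one simulation condition."""

    condition: str = "WT"
    coupling: str = "NC"
    calcium: CalciumParams = field(default_factory=CalciumParams)
    coupling_params: CouplingParams = field(default_factory=CouplingParams)
    ip3_metabolism: IP3MetabolismParams = field(default_factory=IP3MetabolismParams)
    ip3r: IP3RGatingParams = field(default_factory=IP3RGatingParams)
    vgcc: VGCCParams = field(default_factory=VGCCParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    release: ReleaseParams = field(default_factory=ReleaseParams)

    def to_dict(self) -> dict:
        def enc(obj):
            d = {}
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                d[f.name] = list(v) if isinstance(v, tuple) else v
            return d
        return {
            "condition": self.condition,
            "coupling": self.coupling,
            "calcium": enc(self.calcium),
            "coupling_params": enc(self.coupling_params),
            "ip3_metabolism": enc(self.ip3_metabolism),
            "ip3r": enc(self.ip3r),
            "vgcc": enc(self.vgcc),
            "membrane": enc(self.membrane),
            "release": enc(self.release),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        kw: dict[str, Any] = {"condition": d.get("condition", "WT"),
                              "coupling": d.get("coupling", "NC")}
        for name, typ in (("calcium", CalciumParams),
                          ("coupling_params", CouplingParams),
                          ("ip3_metabolism", IP3MetabolismParams),
                          ("ip3r", IP3RGatingParams),
                          ("vgcc", VGCCParams),
                          ("membrane", MembraneParams),
                          ("release", ReleaseParams)):
            sub = dict(d.get(name, {}))
            for f in dataclasses.fields(typ):
                if f.name in sub and isinstance(getattr(typ(), f.name), tuple):
                    sub[f.name] = tuple(sub[f.name])
            kw[name] = typ(**sub)
        return cls(**kw)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_json(cls, s: str) -> "ParameterSet":
        return cls.from_dict(json.loads(s))


def load_parameters(config: dict | str | None = None, *,
                    condition: str | None = None,
                    coupling: str | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a configuration.

    ``config`` may be a dict (sections ``condition``, ``coupling``,
    ``overrides``), a JSON/TOML string or a path to such a file.  Explicit
    keyword arguments win over the config.  Unspecified fields take the
    table defaults for the selected presets.

    Raises ``ValueError`` on unknown condition/coupling tags or if the
    resolved set violates any invariant.
    """
    cfg: dict = {}
    if isinstance(config, dict):
        cfg = config
    elif isinstance(config, str):
        text = config
        if "\n" not in config and len(config) < 4096:
            try:
                with open(config) as fh:
                    text = fh.read()
            except OSError:
                pass
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError:
            import tomllib
            cfg = tomllib.loads(text)
    elif config is not None:
        raise TypeError(f"unsupported config type: {type(config)!r}")

    cond = (condition or cfg.get("condition", "WT")).upper()
    coup = (coupling or cfg.get("coupling", "NC")).upper()
    if cond not in ("WT", "AD"):
        raise ValueError(f"unknown condition {cond!r}: expected WT or AD")
    if coup not in ("NC", "HC"):
        raise ValueError(f"unknown coupling {coup!r}: expected NC or HC")

    ps = ParameterSet(condition=cond, coupling=coup)
    for k, v in IP3R_PRESETS[cond].items():
        setattr(ps.ip3r, k, v)
    ps.ip3r.condition = cond
    for k, v in IP3_METABOLISM_PRESETS[cond].items():
        setattr(ps.ip3_metabolism, k, v)
    for k, v in COUPLING_PRESETS[coup].items():
        setattr(ps.coupling_params, k, v)
    ps.coupling_params.preset = coup

    overrides = cfg.get("overrides", {})
    for group, fields in overrides.items():
        attr = "coupling_params" if group == "coupling" else group
        if attr not in ("calcium", "coupling_params", "ip3_metabolism",
                        "ip3r", "vgcc", "membrane", "release"):
            raise ValueError(f"unknown parameter group {group!r}")
        obj = getattr(ps, attr)
        valid = {f.name for f in dataclasses.fields(obj)}
        for k, v in fields.items():
            if k not in valid:
                raise ValueError(f"unknown field {group}.{k}")
            setattr(obj, k, tuple(v) if isinstance(getattr(obj, k), tuple) else v)

    violations = validate(ps)
    if violations:
        raise ValueError("invalid parameter set:\n  " + "\n  ".join(violations))
    return ps


def validate(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid)."""
    v: list[str] = []

    def positive(obj, names, group):
        for n in names:
            x = getattr(obj, n)
            if not (isinstance(x, (int, float)) and x > 0):
                v.append(f"{group}.{n}: must be > 0 (got {x!r})")

    ca = params.calcium
    positive(ca, ["Jleak_in", "Vleak_in", "k_IPR_diff", "k_VGCC_diff",
                  "k_ER_leak", "k_IPR", "V_PMCA", "K_PMCA", "n_P",
                  "V_SERCA", "K_SERCA", "n_S", "delta1", "delta2", "delta3"],
             "calcium")
    if ca.N_IPR < 1:
        v.append(f"calcium.N_IPR: must be >= 1 (got {ca.N_IPR})")

    cp = params.coupling_params
    positive(cp, ["Vc", "kbar", "Kc"], "coupling")

    m = params.ip3_metabolism
    positive(m, ["V0", "VQ", "KQ", "K_IP3k", "K_PLC", "k3k", "k5p",
                 "kf_PLC", "kb_PLC", "kf_G", "kb_G", "VR", "KR"],
             "ip3_metabolism")
    if m.Abeta < 0:
        v.append(f"ip3_metabolism.Abeta: must be >= 0 (got {m.Abeta})")

    r = params.ip3r
    positive(r, ["a1", "nO", "KOd", "a2", "nA", "KAd", "a3", "nI", "KId",
                 "j01", "j12", "j22", "j23", "j45", "jt01", "jt45"], "ip3r")
    if r.gating_ligand not in ("cytosol", "microdomain"):
        v.append(f"ip3r.gating_ligand: unknown value {r.gating_ligand!r}")

    g = params.vgcc
    for i in range(4):
        if g.alpha0[i] <= 0:
            v.append(f"vgcc.alpha0[{i}]: must be > 0")
        if g.beta0[i] <= 0:
            v.append(f"vgcc.beta0[{i}]: must be > 0")
    positive(g, ["g", "cluster_area", "AZ_area", "N_AZ", "V_eff"], "vgcc")
    if g.N_VGCC < 0:
        v.append(f"vgcc.N_VGCC: must be >= 0 (got {g.N_VGCC})")

    mem = params.membrane
    for n in ("Cm", "gNa", "gK", "gNaleak", "gKleak", "gClleak", "gAHP"):
        if getattr(mem, n) < 0:
            v.append(f"membrane.{n}: must be >= 0")
    positive(mem, ["phi", "area_cm2"], "membrane")

    rel = params.release
    positive(rel, ["kmob", "kdemob", "kpriming", "kunpr", "kattach",
                   "kdetach", "kRF", "alpha", "beta", "lam", "delta",
                   "gamma2"], "release")
    if rel.gamma1 < 0:
        v.append("release.gamma1: must be >= 0")
    if not 0 < rel.b <= 1:
        v.append(f"release.b: cooperativity must satisfy 0 < b <= 1 (got {rel.b})")
    if rel.a <= 0:
        v.append(f"release.a: must be > 0 (got {rel.a})")
    if rel.N_sites < 1:
        v.append(f"release.N_sites: must be >= 1 (got {rel.N_sites})")
    if rel.N_reserve < 0:
        v.append(f"release.N_reserve: must be >= 0 (got {rel.N_reserve})")
    return v
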