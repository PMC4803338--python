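"""Ion-channel models, density profiles, and the dendritic calcium pool.

Six voltage- (or calcium-) gated conductances are implemented in standard
Hodgkin-Huxley form, re-derived from the published hippocampal/cortical
channel families they belong to:

* ``Na``    -- transient sodium, m^3 h, trap-form rates; the activation curve
  can be shifted per compartment (+5 mV in dendrites, -10 mV in half of the
  axonal channels).
* ``K_DR``  -- delayed-rectifier potassium, n.
* ``K_A``   -- A-type potassium, n*l, with a thermodynamic activation whose
  effective slope steepens below -40 mV and a linearly voltage-dependent
  inactivation time constant.
* ``Ca_H``  -- high-voltage-activated calcium, m^2 h.
* ``Ca_L``  -- low-threshold (T-type-like) calcium, m^2 h, restricted to the
  calcium-spike initiation zone.
* ``K_Ca``  -- calcium-activated potassium, a single Hill-activated gate on
  the intracellular calcium pool.

Reversal potentials are fixed: E_Na = +60 mV, E_K = -80 mV, E_Ca = +140 mV.
Rates are given at 30 degrees C (Q10 factors folded into the defaults).

A handful of kinetic constants that the underlying model family leaves open
(the low-threshold calcium activation/inactivation midpoints and time-constant
scales, the K_Ca half-activation, and the calcium-pool coupling) are collected
in :class:`KineticParams`; they were calibrated once so the assembled cell
reproduces the benchmark behaviors of the modeled pyramidal neuron (a
threshold 0.3 nA somatic stimulus, bAP attenuation along the apical tree, a
~25 nS critical inhibitory conductance at 90 um, and an 8 nS distal threshold
for calcium-spike initiation), and are not meant to be tuned per experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .cable import CableGrid

__all__ = [
    "KineticParams",
    "ChannelDensityParams",
    "DensityMap",
    "ka_density",
    "assemble_channel_distribution",
    "membrane_current",
    "gating_steady_states",
]

F_COULOMB_PER_MOL = 96485.0


# ---------------------------------------------------------------------------
# kinetic parameter block (free constants, see module docstring)
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Calibrated kinetic constants passed into the integration kernel."""

    qt_na: float = 0.8               # overall Na rate scale at 30 C
    qt_kdr: float = 1.0
    qt_ka: float = 5.0 ** 0.6        # Q10=5, 24 -> 30 C
    cal_m_vhalf: float = -24.49      # mV, low-threshold Ca activation midpoint
    cal_m_k: float = 4.0             # mV, activation slope
    cal_h_vhalf: float = -35.0       # mV, inactivation midpoint
    cal_h_k: float = 6.0             # mV, inactivation slope
    cal_tm_scale: float = 1.0        # scale on activation time constant
    cal_th_scale: float = 1.0        # scale on inactivation time constant
    kca_kd: float = 0.4              # mM, K_Ca half-activation on the pool
    kca_tau: float = 8.0             # ms
    ca_gamma: float = 1.0            # dimensionless influx coupling
    ca_tau: float = 100.0            # ms, pool relaxation
    ca_rest: float = 5e-5            # mM (50 nM)
    ca_depth_um: float = 0.1         # um, submembrane shell depth
    na_tha: float = -33.9            # mV, Na activation anchor (pre-shift)
    na_hvhalf: float = -53.0         # mV, Na inactivation midpoint
    ka_vhalf: float = 11.0           # mV, A-type activation anchor
    ka_tau_scale: float = 1.0        # scale on A-type activation tau
    na_htau_scale: float = 1.0       # <1 slows, >1 speeds Na inactivation
    ka_lvhalf: float = -56.0         # mV, A-type inactivation midpoint
    ka_ltau_rec: float = 2.1         # ms, A-type recovery (deinactivation)
    na_hrec_speedup: float = 3.0     # fold speedup of Na deinactivation

    def to_array(self) -> np.ndarray:
        return np.array([
            self.qt_na, self.qt_kdr, self.qt_ka,
            self.cal_m_vhalf, self.cal_m_k, self.cal_h_vhalf, self.cal_h_k,
            self.cal_tm_scale, self.cal_th_scale,
            self.kca_kd, self.kca_tau,
            self.ca_gamma, self.ca_tau, self.ca_rest, self.ca_depth_um,
            self.na_tha, self.na_hvhalf, self.ka_vhalf, self.ka_tau_scale,
            self.na_htau_scale, self.ka_lvhalf, self.ka_ltau_rec,
            self.na_hrec_speedup,
        ])


# ---------------------------------------------------------------------------
# rate functions (numba scalar kernels, also callable from Python)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _trap(v: float, th: float, a: float, q: float) -> float:
    """Singularity-safe a*(v-th)/(1-exp(-(v-th)/q))."""
    x = v - th
    if abs(x / q) < 1e-6:
        return a * q * (1.0 + x / (2.0 * q))
    return a * x / (1.0 - math.exp(-x / q))


@njit(cache=True)
def na_gates(v: float, shift: float, qt: float,
             tha_base: float = -30.0, hvhalf: float = -50.0,
             htau_scale: float = 1.0):
    """Transient Na: returns (minf, mtau, hinf, htau).

    ``shift`` moves the activation midpoint (positive = harder to open);
    inactivation is left in place.
    """
    tha = tha_base + shift
    am = _trap(v, tha, 0.4, 7.2)
    bm = _trap(-v, -tha, 0.124, 7.2)
    minf = am / (am + bm)
    mtau = 1.0 / ((am + bm) * qt)
    if mtau < 0.02:
        mtau = 0.02
    ah = _trap(v, -45.0, 0.03, 1.5)
    bh = _trap(-v, 45.0, 0.01, 1.5)
    htau = 1.0 / ((ah + bh) * qt * htau_scale)
    if htau < 0.4:
        htau = 0.4
    hinf = 1.0 / (1.0 + math.exp((v - hvhalf) / 4.0))
    return minf, mtau, hinf, htau


@njit(cache=True)
def kdr_gates(v: float, qt: float):
    """Delayed rectifier K: returns (ninf, ntau)."""
    ninf = 1.0 / (1.0 + math.exp(-(v - 13.0) / 8.7))
    ntau = (0.5 + 4.0 / (1.0 + math.exp((v + 20.0) / 20.0))) / qt
    return ninf, ntau


@njit(cache=True)
def ka_gates(v: float, qt: float, vhalf: float = 11.0,
             tau_scale: float = 1.0, lvhalf: float = -56.0):
    """A-type K (proximal form): returns (ninf, ntau, linf, ltau)."""
    zeta = -1.5 - 1.0 / (1.0 + math.exp((v + 40.0) / 5.0))
    alpn = math.exp(0.0383 * zeta * (v - vhalf))
    betn = math.exp(0.0383 * zeta * 0.55 * (v - vhalf))
    ninf = 1.0 / (1.0 + alpn)
    ntau = tau_scale * betn / (qt * 0.05 * (1.0 + alpn))
    if ntau < 0.1:
        ntau = 0.1
    linf = 1.0 / (1.0 + math.exp((v - lvhalf) / 8.7))
    ltau = 0.26 * (v + 50.0)
    if ltau < 2.0:
        ltau = 2.0
    return ninf, ntau, linf, ltau


@njit(cache=True)
def cah_gates(v: float):
    """High-voltage-activated Ca: returns (minf, mtau, hinf, htau)."""
    if abs(v + 27.0) < 1e-6:
        am = 0.055 * 3.8
    else:
        am = 0.055 * (-27.0 - v) / (math.exp((-27.0 - v) / 3.8) - 1.0)
    bm = 0.94 * math.exp((-75.0 - v) / 17.0)
    minf = am / (am + bm)
    mtau = 1.0 / (am + bm)
    ah = 0.000457 * math.exp((-13.0 - v) / 50.0)
    bh = 0.0065 / (math.exp((-v - 15.0) / 28.0) + 1.0)
    hinf = ah / (ah + bh)
    htau = 1.0 / (ah + bh)
    return minf, mtau, hinf, htau


@njit(cache=True)
def cal_gates(v: float, vm: float, km: float, vh: float, kh: float,
              tms: float, ths: float):
    """Low-threshold (T-type-like) Ca: returns (minf, mtau, hinf, htau)."""
    minf = 1.0 / (1.0 + math.exp(-(v - vm) / km))
    mtau = tms * (0.6 + 1.0 / (math.exp(-(v + 132.0) / 16.7)
                               + math.exp((v + 16.8) / 18.2)))
    if mtau < 0.25:
        mtau = 0.25
    hinf = 1.0 / (1.0 + math.exp((v - vh) / kh))
    htau = ths * (20.0 + 60.0 / (1.0 + math.exp((v + 60.0) / 8.0)))
    return minf, mtau, hinf, htau


@njit(cache=True)
def kca_gate(ca: float, kd: float, tau: float):
    """Ca-activated K: Hill (n=2) activation on the pool; returns (zinf, ztau)."""
    c2 = ca * ca
    zinf = c2 / (c2 + kd * kd)
    return zinf, tau


def gating_steady_states(v: float, kp: KineticParams | None = None) -> dict:
    """Steady-state values of every gate at voltage ``v`` (property tests)."""
    kp = kp or KineticParams()
    minf, _, hinf, _ = na_gates(v, 0.0, kp.qt_na, kp.na_tha, kp.na_hvhalf,
                                kp.na_htau_scale)
    ninf, _ = kdr_gates(v, kp.qt_kdr)
    kan, _, kal, _ = ka_gates(v, kp.qt_ka, kp.ka_vhalf, kp.ka_tau_scale,
                              kp.ka_lvhalf)
    chm, _, chh, _ = cah_gates(v)
    clm, _, clh, _ = cal_gates(v, kp.cal_m_vhalf, kp.cal_m_k,
                               kp.cal_h_vhalf, kp.cal_h_k,
                               kp.cal_tm_scale, kp.cal_th_scale)
    return {"na_m": minf, "na_h": hinf, "kdr_n": ninf,
            "ka_n": kan, "ka_l": kal, "cah_m": chm, "cah_h": chh,
            "cal_m": clm, "cal_h": clh}


def gating_time_constants(v: float, kp: KineticParams | None = None) -> dict:
    kp = kp or KineticParams()
    _, mt, _, ht = na_gates(v, 0.0, kp.qt_na, kp.na_tha, kp.na_hvhalf,
                            kp.na_htau_scale)
    _, nt = kdr_gates(v, kp.qt_kdr)
    _, kant, _, kalt = ka_gates(v, kp.qt_ka, kp.ka_vhalf, kp.ka_tau_scale,
                                kp.ka_lvhalf)
    _, chmt, _, chht = cah_gates(v)
    _, clmt, _, clht = cal_gates(v, kp.cal_m_vhalf, kp.cal_m_k,
                                 kp.cal_h_vhalf, kp.cal_h_k,
                                 kp.cal_tm_scale, kp.cal_th_scale)
    return {"na_m": mt, "na_h": ht, "kdr_n": nt, "ka_n": kant, "ka_l": kalt,
            "cah_m": chmt, "cah_h": chht, "cal_m": clmt, "cal_h": clht}


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

@dataclass
class ChannelDensityParams:
    """Maximal conductance densities (S/cm^2) and their spatial rules."""

    gna_dend: float = 0.009
    gkdr: float = 0.01
    gka_base: float = 0.029        # somatic/proximal A-type density
    ka_fold: float = 5.0           # fold increase reached at ka_range
    ka_range_um: float = 500.0
    ka_clamp: bool = False         # clamp the gradient beyond ka_range
    gcah_dend: float = 0.00015
    gkca_dend: float = 0.00025
    gcal_zone: float = 0.005
    cah_zone_fold: float = 3.0
    soma_ca_fold: float = 2.0      # Ca_H and K_Ca soma/dendrite ratio
    zone_um: tuple = (500.0, 750.0)
    gna_axon_total: float = 0.6
    axon_shift_mv: float = -10.0   # applied to 50% of axonal Na
    axon_base_shift_mv: float = 0.75  # initiation-threshold offset vs soma
    dend_na_shift_mv: float = 5.0
    e_na: float = 60.0
    e_k: float = -80.0
    e_ca: float = 140.0


def ka_density(distance_um: float, params: ChannelDensityParams | None = None
               ) -> float:
    """A-type K density (S/cm^2) at a given path distance from the soma.

    Linear from the somatic value to ``ka_fold`` times that value at
    ``ka_range_um``.  By default the gradient continues beyond that range
    (the calibrated cell needs the extra distal A-current to keep single
    backpropagating spikes out of the calcium zone); ``ka_clamp=True``
    freezes the density at its 500 um value instead.
    """
    p = params or ChannelDensityParams()
    if distance_um < 0:
        raise ValueError("distance must be >= 0")
    d = min(distance_um, p.ka_range_um) if p.ka_clamp else distance_um
    return p.gka_base * (1.0 + (p.ka_fold - 1.0) * d / p.ka_range_um)


@dataclass
class DensityMap:
    """Per-node maximal conductance densities (S/cm^2) plus Na shifts (mV)."""

    gna1: np.ndarray
    shift1: np.ndarray
    gna2: np.ndarray           # second axonal Na population
    shift2: np.ndarray
    gkdr: np.ndarray
    gka: np.ndarray
    gcah: np.ndarray
    gcal: np.ndarray
    gkca: np.ndarray
    ca_present: np.ndarray     # bool: node carries the calcium pool
    params: ChannelDensityParams

    def scaled(self, **fold) -> "DensityMap":
        """Copy with whole-array fold changes, e.g. ``scaled(gcal=0.0)``."""
        import copy
        new = copy.deepcopy(self)
        for name, factor in fold.items():
            setattr(new, name, getattr(new, name) * factor)
        return new


def assemble_channel_distribution(grid: CableGrid,
                                  params: ChannelDensityParams | None = None
                                  ) -> DensityMap:
    """Distribute channels over the discretized tree.

    Dendrites carry uniform Na (activation shifted +5 mV) and K_DR, the
    distance-graded A-type K, and the calcium system (Ca_H, K_Ca, pool);
    the 500-750 um apical zone additionally gets 3x Ca_H and the
    low-threshold Ca; the soma doubles Ca_H and K_Ca; the axon carries only
    Na (two half-populations, one shifted -10 mV) and K_DR.
    """
    p = params or ChannelDensityParams()
    n = grid.n_nodes
    morph = grid.morph
    gna1 = np.zeros(n)
    shift1 = np.zeros(n)
    gna2 = np.zeros(n)
    shift2 = np.zeros(n)
    gkdr = np.full(n, p.gkdr)
    gka = np.zeros(n)
    gcah = np.zeros(n)
    gcal = np.zeros(n)
    gkca = np.zeros(n)
    ca_present = np.zeros(n, dtype=np.bool_)

    z0, z1 = p.zone_um
    for i in range(n):
        stype = morph.sections[grid.section[i]].stype
        d = grid.dist_um[i]
        if stype == "axon":
            gna1[i] = p.gna_axon_total / 2.0
            gna2[i] = p.gna_axon_total / 2.0
            shift1[i] = p.axon_base_shift_mv
            shift2[i] = p.axon_base_shift_mv + p.axon_shift_mv
        elif stype == "soma":
            gna1[i] = p.gna_dend
            gka[i] = p.gka_base
            gcah[i] = p.gcah_dend * p.soma_ca_fold
            gkca[i] = p.gkca_dend * p.soma_ca_fold
            ca_present[i] = True
        else:
            gna1[i] = p.gna_dend
            shift1[i] = p.dend_na_shift_mv
            # basal sections keep the somatic A-type value; the gradient is
            # an apical fit
            gka[i] = p.gka_base if stype == "basal" else ka_density(d, p)
            in_zone = stype == "apical" and z0 <= d <= z1
            gcah[i] = p.gcah_dend * (p.cah_zone_fold if in_zone else 1.0)
            gkca[i] = p.gkca_dend
            if in_zone:
                gcal[i] = p.gcal_zone
            ca_present[i] = True
    return DensityMap(gna1, shift1, gna2, shift2, gkdr, gka, gcah, gcal,
                      gkca, ca_present, p)


def parameter_table(density_params: ChannelDensityParams | None = None,
                    kinetics: KineticParams | None = None) -> dict:
    """Machine-readable table of every model parameter (densities in S/cm^2,
    reversals in mV, compartment rules spelled out)."""
    p = density_params or ChannelDensityParams()
    k = kinetics or KineticParams()
    return {
        "reversal_potentials_mV": {"E_Na": p.e_na, "E_K": p.e_k,
                                   "E_Ca": p.e_ca, "E_leak": -70.0,
                                   "E_inhibition": -73.0},
        "densities_S_per_cm2": {
            "soma": {"g_Na": p.gna_dend, "g_KDR": p.gkdr,
                     "g_KA": p.gka_base,
                     "g_CaH": p.gcah_dend * p.soma_ca_fold,
                     "g_KCa": p.gkca_dend * p.soma_ca_fold},
            "dendrite": {"g_Na": p.gna_dend, "g_KDR": p.gkdr,
                         "g_KA": f"{p.gka_base} increasing "
                                 f"{p.ka_fold}-fold to {p.ka_range_um} um",
                         "g_CaH": p.gcah_dend, "g_KCa": p.gkca_dend},
            "calcium_zone_500_750_um": {
                "g_CaH": p.gcah_dend * p.cah_zone_fold,
                "g_CaL": p.gcal_zone},
            "axon": {"g_Na_total": p.gna_axon_total,
                     "shifted_fraction": 0.5,
                     "shift_mV": p.axon_shift_mv},
        },
        "voltage_shifts_mV": {"dendritic_Na_activation": p.dend_na_shift_mv,
                              "axonal_Na_half_population": p.axon_shift_mv},
        "kinetics": asdict(k),
        "passive": {"C_m_uF_cm2": 0.75, "R_a_ohm_cm": 150.0,
                    "R_m_ohm_cm2": 40_000.0, "E_L_mV": -70.0},
    }


# ---------------------------------------------------------------------------
# current summation (spec surface + oracle target)
# ---------------------------------------------------------------------------

#: gate exponents of each channel's open probability product
GATE_EXPONENTS = {
    "na": (("m", 3), ("h", 1)),
    "kdr": (("n", 1),),
    "ka": (("n", 1), ("l", 1)),
    "cah": (("m", 2), ("h", 1)),
    "cal": (("m", 2), ("h", 1)),
    "kca": (("z", 1),),
}


def membrane_current(v: float, gates: dict, densities: dict,
                     rm_ohm_cm2: float = 40_000.0, e_leak: float = -70.0,
                     params: ChannelDensityParams | None = None) -> dict:
    """Per-channel membrane current densities (mA/cm^2).

    ``gates`` maps "<channel>_<gate>" to states in [0, 1]; ``densities`` maps
    channel name to S/cm^2.  Each channel contributes
    g * prod(gates^exponent) * (V - E_rev); the leak contributes
    (V - E_L) / R_m.
    """
    p = params or ChannelDensityParams()
    rev = {"na": p.e_na, "kdr": p.e_k, "ka": p.e_k,
           "cah": p.e_ca, "cal": p.e_ca, "kca": p.e_k}
    out = {}
    for chan, g in densities.items():
        if chan not in GATE_EXPONENTS:
            raise KeyError(f"unknown channel {chan!r}")
        open_p = 1.0
        for gate, expo in GATE_EXPONENTS[chan]:
            s = gates[f"{chan}_{gate}"]
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"gate {chan}_{gate} outside [0, 1]")
            open_p *= s ** expo
        out[chan] = g * open_p * (v - rev[chan])
    out["leak"] = (v - e_leak) / rm_ohm_cm2  # mV/(Ohm*cm^2) = mA/cm^2
    return out
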