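"""Implicit integration of the branched cable equation with active channels.

The spatially discretized cable is advanced with a staggered backward-Euler
scheme: gating variables are updated by exponential Euler at the current
voltage, then the voltage step solves the branched tridiagonal system (Hines
elimination over the depth-first node ordering, so the solve is exact and
unconditionally stable).  Synaptic conductances enter the implicit step as
linear conductance terms evaluated at the step midpoint.

The default time step is 0.1 ms.  That is coarse for action potentials, so a
refinement-stability property (halving dt changes bAP peaks by < 2% and flips
no all-or-none classification) is part of the test suite.

State is initialized at -70 mV with gates at steady state, followed by a
200 ms settling period before t = 0 of any protocol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from . import channels as ch
from .cable import CableGrid, discretize
from .channels import (ChannelDensityParams, DensityMap, KineticParams,
                       assemble_channel_distribution, F_COULOMB_PER_MOL)
from .morphology import Morphology, SiteAddress, build_simplified_pyramidal
from .stimuli import (Exp2SynSpec, ExpSynSpec, StepCurrentSpec,
                      StimulusProtocol, exp2_waveform, exp_waveform)

__all__ = ["SimulationSpec", "Recording", "NeuronCell", "build_neuron",
           "simulate"]

QUANTITIES = ("V", "I_Ca", "Ca", "g_syn")


@dataclass
class SimulationSpec:
    """What to integrate and what to record.

    probes: list of (label, SiteAddress, quantity) with quantity in
    {"V", "I_Ca", "Ca", "g_syn"}.  I_Ca is reported as a current density in
    mA/cm^2, Ca in mM, g_syn in uS.
    """

    duration: float
    dt: float = 0.1
    probes: list = field(default_factory=list)
    v_init: float = -70.0
    settle_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")
        for label, site, qty in self.probes:
            if qty not in QUANTITIES:
                raise ValueError(f"unknown probe quantity {qty!r}")


@dataclass
class Recording:
    """Time series at the requested probes, all on a shared grid."""

    t: np.ndarray
    series: dict
    meta: dict = field(default_factory=dict)

    def get(self, label: str, quantity: str = "V") -> np.ndarray:
        return self.series[(label, quantity)]

    def __getitem__(self, key) -> np.ndarray:
        return self.series[key]

    def labels(self) -> list:
        return sorted({k[0] for k in self.series})

    def to_frame(self):
        """Long-format table (time, probe, quantity, value)."""
        import pandas as pd
        rows = []
        for (label, qty), values in self.series.items():
            rows.append(pd.DataFrame({"time_ms": self.t, "probe": label,
                                      "quantity": qty, "value": values}))
        return pd.concat(rows, ignore_index=True)


class NeuronCell:
    """An assembled neuron: morphology + discretization + channel densities."""

    def __init__(self, morph: Morphology | None = None,
                 density_params: ChannelDensityParams | None = None,
                 kinetics: KineticParams | None = None,
                 densities: DensityMap | None = None) -> None:
        self.morph = morph or build_simplified_pyramidal()
        self.grid = discretize(self.morph)
        self.kin = kinetics or KineticParams()
        self.dens = densities if densities is not None else \
            assemble_channel_distribution(self.grid, density_params)

    def with_densities(self, dens: DensityMap) -> "NeuronCell":
        cell = NeuronCell.__new__(NeuronCell)
        cell.morph, cell.grid, cell.kin = self.morph, self.grid, self.kin
        cell.dens = dens
        return cell

    def param_hash(self) -> str:
        payload = repr((asdict(self.kin), asdict(self.dens.params),
                        [(s.name, s.length, s.diameter, s.nseg)
                         for s in self.morph.sections.values()]))
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def build_neuron(morph_overrides: dict | None = None,
                 density_params: ChannelDensityParams | None = None,
                 kinetics: KineticParams | None = None) -> NeuronCell:
    """Assemble the default simplified pyramidal cell."""
    return NeuronCell(build_simplified_pyramidal(morph_overrides),
                      density_params, kinetics)


# ---------------------------------------------------------------------------
# protocol compilation
# ---------------------------------------------------------------------------

def _compile_protocol(cell: NeuronCell, protocol: StimulusProtocol,
                      dt: float, n_steps: int, settle_steps: int):
    """Evaluate every event on the step grid; group synapses by (node, E)."""
    grid = cell.grid
    t_mid = (np.arange(n_steps) + 0.5) * dt
    syn: dict[tuple, np.ndarray] = {}
    inj: dict[int, np.ndarray] = {}
    for ev in protocol:
        if isinstance(ev, StepCurrentSpec):
            node = grid.node_index(ev.site)
            # exact overlap of each step with the pulse
            lo = np.clip(ev.onset_ms, t_mid - dt / 2, t_mid + dt / 2)
            hi = np.clip(ev.onset_ms + ev.duration_ms, t_mid - dt / 2,
                         t_mid + dt / 2)
            wave = ev.amplitude_na * (hi - lo) / dt
            inj[node] = inj.get(node, 0.0) + wave
        elif isinstance(ev, (Exp2SynSpec, ExpSynSpec)):
            node = grid.node_index(ev.site)
            key = (node, float(ev.e_rev))
            wave = (exp2_waveform(t_mid, ev) if isinstance(ev, Exp2SynSpec)
                    else exp_waveform(t_mid, ev))
            syn[key] = syn.get(key, 0.0) + wave
        else:
            raise TypeError(f"unknown protocol event {type(ev).__name__}")

    pad = np.zeros(settle_steps)
    if syn:
        syn_node = np.array([k[0] for k in syn], dtype=np.int64)
        syn_e = np.array([k[1] for k in syn])
        syn_g = np.stack([np.concatenate([pad, g]) for g in syn.values()])
    else:
        syn_node = np.zeros(0, dtype=np.int64)
        syn_e = np.zeros(0)
        syn_g = np.zeros((0, settle_steps + n_steps))
    if inj:
        inj_node = np.array(list(inj), dtype=np.int64)
        inj_i = np.stack([np.concatenate([pad, w]) for w in inj.values()])
    else:
        inj_node = np.zeros(0, dtype=np.int64)
        inj_i = np.zeros((0, settle_steps + n_steps))
    return syn_node, syn_e, syn_g, inj_node, inj_i


# ---------------------------------------------------------------------------
# the integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(dt, total_steps, settle_steps,
               parent, g_ax, c, g_leak, e_leak,
               gna1, sh1, gna2, sh2, gkdr, gka, gcah, gcal, gkca,
               ca_on, phi,
               ena, ek, eca, kp,
               syn_node, syn_e, syn_g,
               inj_node, inj_i,
               probe_nodes, v_init):
    n = parent.size
    n_rec = total_steps - settle_steps + 1
    n_probes = probe_nodes.size
    vp = np.zeros((n_probes, n_rec))
    icap = np.zeros((n_probes, n_rec))
    cap = np.zeros((n_probes, n_rec))

    qtna, qtk, qtka = kp[0], kp[1], kp[2]
    calmv, calmk, calhv, calhk = kp[3], kp[4], kp[5], kp[6]
    tms, ths = kp[7], kp[8]
    kcakd, kcatau = kp[9], kp[10]
    catau, carest = kp[12], kp[13]
    na_tha, na_hv = kp[15], kp[16]
    ka_vh, ka_ts = kp[17], kp[18]
    na_hts = kp[19]
    ka_lv = kp[20]
    ka_lrec = kp[21]
    na_hrec = kp[22]

    v = np.full(n, v_init)
    m1 = np.zeros(n); h1 = np.zeros(n)
    m2 = np.zeros(n); h2 = np.zeros(n)
    nk = np.zeros(n)
    ak = np.zeros(n); lk = np.zeros(n)
    mch = np.zeros(n); hch = np.zeros(n)
    mcl = np.zeros(n); hcl = np.zeros(n)
    z = np.zeros(n)
    ca = np.full(n, carest)
    for i in range(n):
        mi, _, hi, _ = ch.na_gates(v_init, sh1[i], qtna, na_tha, na_hv, na_hts)
        m1[i], h1[i] = mi, hi
        mi, _, hi, _ = ch.na_gates(v_init, sh2[i], qtna, na_tha, na_hv, na_hts)
        m2[i], h2[i] = mi, hi
        ni, _ = ch.kdr_gates(v_init, qtk)
        nk[i] = ni
        ai, _, li, _ = ch.ka_gates(v_init, qtka, ka_vh, ka_ts, ka_lv)
        ak[i], lk[i] = ai, li
        mi, _, hi, _ = ch.cah_gates(v_init)
        mch[i], hch[i] = mi, hi
        mi, _, hi, _ = ch.cal_gates(v_init, calmv, calmk, calhv, calhk,
                                    tms, ths)
        mcl[i], hcl[i] = mi, hi
        zi, _ = ch.kca_gate(carest, kcakd, kcatau)
        z[i] = zi

    d = np.zeros(n)
    rhs = np.zeros(n)
    ica = np.zeros(n)
    rel_ca = 1.0 - np.exp(-dt / catau)

    # initial record
    for j in range(n_probes):
        i = probe_nodes[j]
        vp[j, 0] = v[i]
        gca = gcah[i] * mch[i] * mch[i] * hch[i] + \
            gcal[i] * mcl[i] * mcl[i] * hcl[i]
        icap[j, 0] = gca * (v[i] - eca)
        cap[j, 0] = ca[i]

    for step in range(total_steps):
        # gate update + quasi-linear membrane terms
        for i in range(n):
            vi = v[i]
            gsum = g_leak[i]
            gesum = g_leak[i] * e_leak

            mi, mt, hi, ht = ch.na_gates(vi, sh1[i], qtna, na_tha, na_hv, na_hts)
            m1[i] = mi + (m1[i] - mi) * np.exp(-dt / mt)
            if hi > h1[i]:
                ht = ht / na_hrec
            h1[i] = hi + (h1[i] - hi) * np.exp(-dt / ht)
            if gna1[i] > 0.0:
                g = gna1[i] * m1[i] * m1[i] * m1[i] * h1[i]
                gsum += g
                gesum += g * ena
            if gna2[i] > 0.0:
                mi, mt, hi, ht = ch.na_gates(vi, sh2[i], qtna, na_tha, na_hv, na_hts)
                m2[i] = mi + (m2[i] - mi) * np.exp(-dt / mt)
                if hi > h2[i]:
                    ht = ht / na_hrec
                h2[i] = hi + (h2[i] - hi) * np.exp(-dt / ht)
                g = gna2[i] * m2[i] * m2[i] * m2[i] * h2[i]
                gsum += g
                gesum += g * ena
            ni, nt = ch.kdr_gates(vi, qtk)
            nk[i] = ni + (nk[i] - ni) * np.exp(-dt / nt)
            if gkdr[i] > 0.0:
                g = gkdr[i] * nk[i]
                gsum += g
                gesum += g * ek
            if gka[i] > 0.0:
                ai, at, li, lt = ch.ka_gates(vi, qtka, ka_vh, ka_ts, ka_lv)
                ak[i] = ai + (ak[i] - ai) * np.exp(-dt / at)
                # recovery from inactivation is slower than inactivation;
                # cumulative inactivation over spike trains boosts late bAPs
                if li > lk[i] and ka_lrec > lt:
                    lt = ka_lrec
                lk[i] = li + (lk[i] - li) * np.exp(-dt / lt)
                g = gka[i] * ak[i] * lk[i]
                gsum += g
                gesum += g * ek
            if gcah[i] > 0.0 or gcal[i] > 0.0:
                mi, mt, hi, ht = ch.cah_gates(vi)
                mch[i] = mi + (mch[i] - mi) * np.exp(-dt / mt)
                hch[i] = hi + (hch[i] - hi) * np.exp(-dt / ht)
                g = gcah[i] * mch[i] * mch[i] * hch[i]
                if gcal[i] > 0.0:
                    mi, mt, hi, ht = ch.cal_gates(vi, calmv, calmk, calhv,
                                                  calhk, tms, ths)
                    mcl[i] = mi + (mcl[i] - mi) * np.exp(-dt / mt)
                    hcl[i] = hi + (hcl[i] - hi) * np.exp(-dt / ht)
                    g += gcal[i] * mcl[i] * mcl[i] * hcl[i]
                gsum += g
                gesum += g * eca
            if gkca[i] > 0.0:
                zi, zt = ch.kca_gate(ca[i], kcakd, kcatau)
                z[i] = zi + (z[i] - zi) * np.exp(-dt / zt)
                g = gkca[i] * z[i]
                gsum += g
                gesum += g * ek

            d[i] = c[i] / dt + gsum
            rhs[i] = c[i] / dt * vi + gesum

        # synapses and injections
        for j in range(syn_node.size):
            i = syn_node[j]
            g = syn_g[j, step]
            d[i] += g
            rhs[i] += g * syn_e[j]
        for j in range(inj_node.size):
            rhs[inj_node[j]] += inj_i[j, step]

        # Hines solve (parents precede children)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            dd = d[i] + g_ax[i]
            f = g_ax[i] / dd
            d[p] += g_ax[i] - f * g_ax[i]
            rhs[p] += f * rhs[i]
            d[i] = dd
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / d[i]

        if not (-500.0 < v[0] < 500.0):
            return step + 1, vp, icap, cap

        # calcium pool
        for i in range(n):
            if ca_on[i] > 0.0:
                g = gcah[i] * mch[i] * mch[i] * hch[i] + \
                    gcal[i] * mcl[i] * mcl[i] * hcl[i]
                ica[i] = g * (v[i] - eca)
                target = carest - phi[i] * ica[i] * catau
                ca[i] += (target - ca[i]) * rel_ca
                if ca[i] < 0.0:
                    ca[i] = 0.0

        if step >= settle_steps:
            r = step - settle_steps + 1
            for j in range(n_probes):
                i = probe_nodes[j]
                vp[j, r] = v[i]
                icap[j, r] = ica[i]
                cap[j, r] = ca[i]

    return 0, vp, icap, cap


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def simulate(cell: NeuronCell, protocol: StimulusProtocol,
             spec: SimulationSpec) -> Recording:
    """Integrate the assembled cell under a stimulation protocol.

    Deterministic for a given (cell, protocol, spec); the only randomness in
    the package lives in protocol generation (jittered inhibition), seeded
    there.
    """
    grid = cell.grid
    dt = spec.dt
    n_steps = int(round(spec.duration / dt))
    settle_steps = int(round(spec.settle_ms / dt))
    total = n_steps + settle_steps

    probes = spec.probes or [("soma", SiteAddress("soma", 0.5), "V")]
    probe_nodes = []
    node_of = {}
    for label, site, qty in probes:
        idx = grid.node_index(grid.morph.resolve(site))
        node_of[(label, qty)] = idx
        probe_nodes.append(idx)
    uniq_nodes = sorted(set(probe_nodes))
    row_of = {node: r for r, node in enumerate(uniq_nodes)}

    syn_node, syn_e, syn_g, inj_node, inj_i = _compile_protocol(
        cell, protocol, dt, n_steps, settle_steps)

    dens, area = cell.dens, grid.area_cm2
    us = 1e6  # S -> uS
    kp = cell.kin.to_array()
    # influx factor: nA -> mM/ms in a submembrane shell of depth ca_depth
    vol_l = area * (cell.kin.ca_depth_um * 1e-4) * 1e-3
    phi = cell.kin.ca_gamma * 1e-9 / (2.0 * F_COULOMB_PER_MOL * vol_l)

    status, vp, icap, cap = _integrate(
        dt, total, settle_steps,
        grid.parent, grid.g_axial_us, grid.c_nf, grid.g_leak_us, grid.e_leak,
        dens.gna1 * area * us, dens.shift1, dens.gna2 * area * us,
        dens.shift2, dens.gkdr * area * us, dens.gka * area * us,
        dens.gcah * area * us, dens.gcal * area * us, dens.gkca * area * us,
        dens.ca_present.astype(np.float64), phi,
        dens.params.e_na, dens.params.e_k, dens.params.e_ca, kp,
        syn_node, syn_e, syn_g, inj_node, inj_i,
        np.array(uniq_nodes, dtype=np.int64), spec.v_init)
    if status != 0:
        t_fail = (status - settle_steps) * dt
        raise FloatingPointError(
            f"non-finite membrane state at t = {t_fail:.2f} ms")

    t = np.arange(n_steps + 1) * dt
    series = {}
    for label, site, qty in probes:
        r = row_of[node_of[(label, qty)]]
        if qty == "V":
            series[(label, qty)] = vp[r].copy()
        elif qty == "I_Ca":
            # nA -> mA/cm^2 current density at the probe node
            node = node_of[(label, qty)]
            series[(label, qty)] = icap[r] * 1e-6 / area[node]
        elif qty == "Ca":
            series[(label, qty)] = cap[r].copy()
        elif qty == "g_syn":
            node = node_of[(label, qty)]
            gsum = np.zeros(n_steps + 1)
            for j, sn in enumerate(syn_node):
                if sn == node:
                    gsum[1:] += syn_g[j, settle_steps:]
            series[(label, qty)] = gsum

    proto_payload = json.dumps(protocol.to_dict(), sort_keys=True,
                               default=str)
    meta = {
        "dt": dt, "duration": spec.duration, "settle_ms": spec.settle_ms,
        "seed": protocol.seed,
        "protocol_hash": hashlib.md5(proto_payload.encode()).hexdigest()[:12],
        "param_hash": cell.param_hash(),
        "protocol": protocol.to_dict(),
    }
    return Recording(t, series, meta)
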