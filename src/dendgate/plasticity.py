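"""Additive STDP, the pairing protocol, and learning-window construction.

The rule is the classic additive exponential window: for a pre/post interval
Dt = t_post - t_pre,

    dw = -A_minus * exp(Dt / tau_minus)   if Dt <= 0
    dw = +A_plus  * exp(-Dt / tau_plus)   if Dt > 0

with A_plus = 0.001, A_minus = 0.00106, tau = 20 ms on both sides.  dw is a
dimensionless fraction of the weight ceiling w_max (the additive-rule
convention); weights are hard-bounded in [0, 0.0001] uS.

The postsynaptic event that defines t_post is the arrival of the coincidence
signal at the synapse: a -20 mV voltage crossing for basal and oblique
synapses (the bAP), and a 0.5 mM crossing of the local calcium pool for the
distal (tuft) synapse, where the calcium spike rather than the bAP governs
plasticity.

A pairing protocol pairs somatic current injection with presynaptic
activation 100 times at 1 Hz.  At 1 Hz every state variable relaxes between
pairings, so each pairing is simulated as an independent trial from the
settled rest state, and the weight update (with clipping) is iterated over
the trial's detected event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import NeuronCell, SimulationSpec, simulate
from .measure import detect_spikes, standard_probes
from .morphology import SiteAddress
from .stimuli import (Exp2SynSpec, ExpSynSpec, StepCurrentSpec,
                      StimulusProtocol)

__all__ = [
    "STDPRule",
    "PostEventDetector",
    "LearningWindow",
    "stdp_delta",
    "run_pairing_protocol",
    "learning_window",
    "distal_calcium_scan",
    "PLASTIC_SYNAPSES",
]


@dataclass(frozen=True)
class STDPRule:
    """Additive STDP parameters (amplitudes dimensionless, tau in ms,
    bounds in uS)."""

    a_plus: float = 0.001
    a_minus: float = 0.00106
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_min: float = 0.0
    w_max: float = 1e-4

    def __post_init__(self) -> None:
        if self.a_plus <= 0 or self.a_minus <= 0:
            raise ValueError("A+/A- must be > 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau must be > 0")
        if not self.w_min < self.w_max:
            raise ValueError("require w_min < w_max")


def stdp_delta(dt_ms: float, rule: STDPRule | None = None) -> float:
    """Weight change (fraction of w_max) for one pre/post pair."""
    rule = rule or STDPRule()
    if dt_ms <= 0:
        return -rule.a_minus * np.exp(dt_ms / rule.tau_minus)
    return rule.a_plus * np.exp(-dt_ms / rule.tau_plus)


#: plastic synapse catalog: path kind, distance from soma (um), detector
#: mode, and drive conductance (nS) used during pairing trials
PLASTIC_SYNAPSES = {
    "basal": ("basal", 75.0, "voltage", 0.001),
    "oblique": ("oblique", 250.0, "voltage", 0.001),
    "distal": ("apical", 530.0, "calcium", 8.0),
}

#: initial weight of a plastic synapse (uS); 0.001 nS as for the small
#: basal/oblique synapses
W_INIT = 1e-6


@dataclass(frozen=True)
class PostEventDetector:
    """How a postsynaptic coincidence event is detected at a synapse."""

    mode: str = "voltage"            # "voltage" | "calcium"
    v_threshold: float = -20.0       # mV, at the synapse
    ca_threshold: float = 0.5        # mM, distal pool

    def __post_init__(self) -> None:
        if self.mode not in ("voltage", "calcium"):
            raise ValueError(f"unknown detector mode {self.mode!r}")

    def events(self, t: np.ndarray, trace: np.ndarray) -> np.ndarray:
        if self.mode == "voltage":
            return detect_spikes(t, trace, self.v_threshold,
                                 refractory_ms=2.0)
        idx = np.flatnonzero((trace[1:] >= self.ca_threshold)
                             & (trace[:-1] < self.ca_threshold))
        return t[idx + 1][:1]  # first crossing only


@dataclass
class LearningWindow:
    """Accumulated, normalized weight change per pairing offset."""

    dt_ms: np.ndarray
    dw_norm: np.ndarray
    dw_raw_us: np.ndarray
    site: str
    condition: str
    norm_constant_us: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"dt_ms": self.dt_ms, "dw_normalized": self.dw_norm,
                             "dw_us": self.dw_raw_us, "site": self.site,
                             "condition": self.condition})


def _soma_spike_latency(cell: NeuronCell) -> float:
    """Delay from somatic step onset to the somatic spike peak (cached)."""
    if not hasattr(cell, "_soma_latency"):
        spec = SimulationSpec(duration=20.0,
                              probes=[("soma", SiteAddress("soma", 0.5), "V")])
        rec = simulate(cell, StimulusProtocol(
            [StepCurrentSpec(onset_ms=5.0)], t_stim=5.0), spec)
        v = rec.get("soma", "V")
        cell._soma_latency = float(rec.t[int(np.argmax(v))]) - 5.0
    return cell._soma_latency


def _pairing_trial(cell: NeuronCell, site: str, dt_ms: float,
                   inhibition: Exp2SynSpec | None,
                   dt_step: float = 0.1) -> tuple[float, np.ndarray]:
    """One pairing: returns (t_pre, detected post-event times)."""
    if site not in PLASTIC_SYNAPSES:
        raise KeyError(f"no plastic synapse defined at {site!r}; "
                       f"choose from {sorted(PLASTIC_SYNAPSES)}")
    kind, dist, mode, g_ns = PLASTIC_SYNAPSES[site]
    syn_site = cell.morph.resolve_um(kind, dist)
    latency = _soma_spike_latency(cell)
    t_pre = 40.0
    t_soma = t_pre + dt_ms - latency
    duration = t_pre + abs(dt_ms) + 60.0

    proto = StimulusProtocol(t_stim=t_soma)
    proto.add(StepCurrentSpec(onset_ms=t_soma))
    proto.add(ExpSynSpec(site=syn_site, g_max_ns=g_ns, onsets=(t_pre,)))
    if inhibition is not None:
        # inhibition onset stored relative to stimulation onset
        onsets = tuple(t_soma + o for o in inhibition.onsets)
        proto.add(Exp2SynSpec(inhibition.site, inhibition.tau_rise,
                              inhibition.tau_decay, inhibition.g_max_ns,
                              inhibition.e_rev, onsets=onsets))

    qty = "Ca" if mode == "calcium" else "V"
    spec = SimulationSpec(duration=duration, dt=dt_step,
                          probes=[("syn", syn_site, qty)])
    rec = simulate(cell, proto, spec)
    detector = PostEventDetector(mode=mode)
    return t_pre, detector.events(rec.t, rec.get("syn", qty))


def accumulate_weight(dw_frac: float, n_pairings: int,
                      rule: STDPRule | None = None,
                      w_init: float = W_INIT) -> float:
    """Apply one pairing's fractional weight change n times with clipping."""
    rule = rule or STDPRule()
    w = w_init
    for _ in range(n_pairings):
        w = min(max(w + dw_frac * rule.w_max, rule.w_min), rule.w_max)
    return w


@dataclass
class PairingResult:
    site: str
    dt_ms: float
    dw_us: float
    w_final_us: float
    post_times: np.ndarray
    pre_time: float


def run_pairing_protocol(cell: NeuronCell, site: str, dt_ms: float,
                         inhibition: Exp2SynSpec | None = None,
                         n_pairings: int = 100, rule: STDPRule | None = None,
                         w_init: float = W_INIT) -> PairingResult:
    """Accumulated weight change of one synapse over the pairing protocol.

    The trial is simulated once (at 1 Hz, trials are independent) and the
    per-trial weight update is applied ``n_pairings`` times sequentially with
    hard-bound clipping.
    """
    rule = rule or STDPRule()
    t_pre, posts = _pairing_trial(cell, site, dt_ms, inhibition)
    dw_frac = sum(stdp_delta(tp - t_pre, rule) for tp in posts)
    w = accumulate_weight(dw_frac, n_pairings, rule, w_init)
    return PairingResult(site, dt_ms, w - w_init, w, posts, t_pre)


def learning_window(cell: NeuronCell, site: str,
                    dt_grid=None, inhibition: Exp2SynSpec | None = None,
                    n_pairings: int = 100, rule: STDPRule | None = None
                    ) -> LearningWindow:
    """STDP window over a grid of pairing offsets, normalized to the maximum
    absolute change of the *uninhibited* window of the same synapse.

    A fully inhibited (flat) window therefore reports exact zeros rather
    than 0/0.
    """
    if dt_grid is None:
        dt_grid = np.linspace(-20.0, 20.0, 9)
    dt_grid = np.asarray(dt_grid, dtype=float)
    raw = np.array([run_pairing_protocol(cell, site, d, inhibition,
                                         n_pairings, rule).dw_us
                    for d in dt_grid])
    if inhibition is None:
        ref = float(np.max(np.abs(raw)))
    else:
        ref_raw = np.array([run_pairing_protocol(cell, site, d, None,
                                                 n_pairings, rule).dw_us
                            for d in dt_grid])
        ref = float(np.max(np.abs(ref_raw)))
    norm = raw / ref if ref > 0 else np.zeros_like(raw)
    return LearningWindow(dt_grid, norm, raw, site,
                          "control" if inhibition is None else "inhibited",
                          ref)


def distal_calcium_scan(cell: NeuronCell, dt_grid=None,
                        inhibition: Exp2SynSpec | None = None):
    """Per-offset distal calcium summary (integral and peak of the pool).

    Because the calcium spike is all-or-none, the integrals over the offset
    grid are bimodally distributed in the uninhibited condition and uniformly
    low under proximal or distal inhibition.
    """
    import pandas as pd
    if dt_grid is None:
        dt_grid = np.linspace(-20.0, 20.0, 9)
    kind, dist, _, g_ns = PLASTIC_SYNAPSES["distal"]
    syn_site = cell.morph.resolve_um(kind, dist)
    latency = _soma_spike_latency(cell)
    rows = []
    for d in np.asarray(dt_grid, dtype=float):
        t_pre = 40.0
        t_soma = t_pre + d - latency
        proto = StimulusProtocol(t_stim=t_soma)
        proto.add(StepCurrentSpec(onset_ms=t_soma))
        proto.add(ExpSynSpec(site=syn_site, g_max_ns=g_ns, onsets=(t_pre,)))
        if inhibition is not None:
            onsets = tuple(t_soma + o for o in inhibition.onsets)
            proto.add(Exp2SynSpec(inhibition.site, inhibition.tau_rise,
                                  inhibition.tau_decay, inhibition.g_max_ns,
                                  inhibition.e_rev, onsets=onsets))
        spec = SimulationSpec(duration=t_pre + abs(d) + 60.0,
                              probes=[("syn", syn_site, "Ca")])
        rec = simulate(cell, proto, spec)
        ca = rec.get("syn", "Ca")
        rows.append({"dt_ms": d,
                     "ca_integral_mM_ms": float(np.trapezoid(ca, rec.t)),
                     "ca_peak_mM": float(ca.max())})
    return pd.DataFrame(rows)
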