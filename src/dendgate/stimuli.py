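"""Synthetic inputs: synapse conductance waveforms and stimulation protocols.

Synapses are conductance-based.  Double-exponential (rise/decay) synapses are
peak-normalized so that ``g_max`` is the actual maximum conductance of a
single event; excitatory synapses use tau 0.5/2 ms with reversal 0 mV,
shunting GABA_A-like inhibition uses tau 0.5/5 ms with reversal -73 mV (at a
resting potential of about -70 mV this barely hyperpolarizes and acts as a
local shunt).  Plastic synapses are single-exponential with tau 3 ms.

Protocol builders cover the full experimental program: somatic threshold
steps (0.3 nA, 2 ms), coincident somatic + distal pairing, distributed trunk
excitation (8 synapses, 140-420 um, 20 nS total), inhibitory pulse trains,
spatio-temporally jittered inhibition, and periodic suprathreshold drive for
critical-frequency scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .morphology import Morphology, SiteAddress

__all__ = [
    "Exp2SynSpec",
    "ExpSynSpec",
    "StepCurrentSpec",
    "StimulusProtocol",
    "exp2_waveform",
    "exp_waveform",
    "make_somatic_step",
    "make_bac_pairing",
    "make_distributed_excitation",
    "make_dendritic_drive",
    "make_inhibitory_train",
    "make_jittered_inhibition",
    "make_frequency_drive",
    "inhibitory_synapse",
]

#: default time constants (ms) and reversals (mV)
EXC_TAU = (0.5, 2.0)
INH_TAU = (0.5, 5.0)
E_EXC = 0.0
E_INH = -73.0
PLASTIC_TAU = 3.0


@dataclass(frozen=True)
class Exp2SynSpec:
    """Double-exponential conductance synapse (difference of exponentials)."""

    site: SiteAddress
    tau_rise: float
    tau_decay: float
    g_max_ns: float
    e_rev: float
    onsets: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.g_max_ns < 0:
            raise ValueError("g_max must be >= 0")

    @property
    def peak_time(self) -> float:
        """Time to peak of a single event (closed form)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)


@dataclass(frozen=True)
class ExpSynSpec:
    """Single-exponential conductance synapse (instant rise)."""

    site: SiteAddress
    tau: float = PLASTIC_TAU
    g_max_ns: float = 0.001
    e_rev: float = E_EXC
    onsets: tuple = ()

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class StepCurrentSpec:
    """Rectangular current injection (defaults: the somatic threshold step)."""

    site: SiteAddress = SiteAddress("soma", 0.5)
    amplitude_na: float = 0.3
    duration_ms: float = 2.0
    onset_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class StimulusProtocol:
    """Ordered collection of stimulation events placed on the tree."""

    events: list = field(default_factory=list)
    seed: int | None = None
    #: reference stimulation onset (ms); measures are reported relative to it
    t_stim: float = 0.0

    def add(self, *events) -> "StimulusProtocol":
        self.events.extend(events)
        return self

    def __iter__(self):
        return iter(self.events)

    def to_dict(self) -> dict:
        def enc(ev):
            d = asdict(ev)
            d["kind"] = type(ev).__name__
            return d
        return {"seed": self.seed, "t_stim": self.t_stim,
                "events": [enc(ev) for ev in self.events]}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        kinds = {"Exp2SynSpec": Exp2SynSpec, "ExpSynSpec": ExpSynSpec,
                 "StepCurrentSpec": StepCurrentSpec}
        events = []
        for e in d["events"]:
            e = dict(e)
            k = kinds[e.pop("kind")]
            if "site" in e:
                e["site"] = SiteAddress(**e["site"])
            if "onsets" in e:
                e["onsets"] = tuple(e["onsets"])
            events.append(k(**e))
        return cls(events, d.get("seed"), d.get("t_stim", 0.0))


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def exp2_waveform(t: np.ndarray, spec: Exp2SynSpec) -> np.ndarray:
    """Conductance (uS) of a double-exponential synapse on a time grid (ms).

    g(t) = g_max * N * (exp(-s/tau_decay) - exp(-s/tau_rise)) per onset, with
    N chosen so a single event peaks exactly at g_max; events superpose.
    """
    t = np.asarray(t, dtype=float)
    tr, td = spec.tau_rise, spec.tau_decay
    tp = spec.peak_time
    norm = 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))
    g = np.zeros_like(t)
    for onset in spec.onsets:
        s = t - onset
        active = s >= 0
        sa = s[active]
        g[active] += norm * (np.exp(-sa / td) - np.exp(-sa / tr))
    return g * spec.g_max_ns * 1e-3  # nS -> uS


def exp_waveform(t: np.ndarray, spec: ExpSynSpec) -> np.ndarray:
    """Conductance (uS) of a single-exponential synapse on a time grid (ms)."""
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    for onset in spec.onsets:
        s = t - onset
        active = s >= 0
        g[active] += np.exp(-s[active] / spec.tau)
    return g * spec.g_max_ns * 1e-3


# ---------------------------------------------------------------------------
# protocol builders
# ---------------------------------------------------------------------------

def _apical(morph: Morphology, um: float) -> SiteAddress:
    return morph.resolve_um("apical", um)


def make_somatic_step(t0: float = 10.0, amplitude_na: float = 0.3,
                      duration_ms: float = 2.0) -> StimulusProtocol:
    """Bare somatic threshold step (the standard bAP trigger)."""
    return StimulusProtocol(
        [StepCurrentSpec(onset_ms=t0, amplitude_na=amplitude_na,
                         duration_ms=duration_ms)],
        t_stim=t0)


def make_bac_pairing(morph: Morphology, dt_ms: float, distal_g_ns: float = 8.0,
                     t0: float = 10.0, with_step: bool = True
                     ) -> StimulusProtocol:
    """Somatic step paired with distal excitation at 530 um after ``dt_ms``.

    With the default 8 nS distal synapse and a positive few-ms delay this
    elicits a distal calcium spike and a two-spike somatic burst; with
    ``with_step=False`` it is the distal-only stimulus (14 nS alone can
    trigger the calcium spike).
    """
    proto = StimulusProtocol(t_stim=t0)
    if with_step:
        proto.add(StepCurrentSpec(onset_ms=t0))
    if distal_g_ns > 0:
        proto.add(Exp2SynSpec(_apical(morph, 530.0), *EXC_TAU, distal_g_ns,
                              E_EXC, onsets=(t0 + dt_ms,)))
    return proto


def make_distributed_excitation(morph: Morphology, total_g_ns: float = 20.0,
                                n: int = 8, onset: float = 10.0,
                                span_um: tuple = (140.0, 420.0)
                                ) -> list[Exp2SynSpec]:
    """n excitatory synapses spread equally over the apical trunk span.

    Positions include both endpoints (n = 1 degenerates to the midpoint);
    each synapse carries total_g/n.  Mimics input from oblique dendrites.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = span_um
    positions = [0.5 * (lo + hi)] if n == 1 else list(np.linspace(lo, hi, n))
    return [Exp2SynSpec(_apical(morph, um), *EXC_TAU, total_g_ns / n, E_EXC,
                        onsets=(onset,)) for um in positions]


def make_dendritic_drive(morph: Morphology, t0: float = 10.0,
                         total_g_ns: float = 20.0) -> StimulusProtocol:
    """Protocol wrapper: distributed trunk excitation as the spike trigger."""
    return StimulusProtocol(make_distributed_excitation(morph, total_g_ns,
                                                        onset=t0), t_stim=t0)


def inhibitory_synapse(morph: Morphology, distance_um: float, g_ns: float,
                       onset: float, kind: str = "apical",
                       n_pulses: int = 1, freq_hz: float = 75.0
                       ) -> Exp2SynSpec:
    """Standard shunting synapse at a path distance from the soma."""
    site = morph.resolve_um(kind, distance_um)
    onsets = tuple(onset + k * 1000.0 / freq_hz for k in range(n_pulses))
    return Exp2SynSpec(site, *INH_TAU, g_ns, E_INH, onsets=onsets)


def make_inhibitory_train(morph: Morphology, n_pulses: int, freq_hz: float,
                          g_ns: float, site: SiteAddress, onset: float
                          ) -> Exp2SynSpec:
    """Inhibitory pulse train: onsets every 1000/freq ms (e.g. 4 @ 75 Hz)."""
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if freq_hz <= 0:
        raise ValueError("freq must be > 0")
    onsets = tuple(onset + k * 1000.0 / freq_hz for k in range(n_pulses))
    return Exp2SynSpec(morph.resolve(site), *INH_TAU, g_ns, E_INH,
                       onsets=onsets)


def make_jittered_inhibition(morph: Morphology, n_syn: int,
                             sigma_space_um: float, sigma_time_ms: float,
                             seed: int, center_um: float = 90.0,
                             mean_onset: float = 12.0, g_each_ns: float = 1.0
                             ) -> list[Exp2SynSpec]:
    """Gaussian-jittered population of 1 nS shunting synapses.

    Positions ~ Normal(center, sigma_space), truncated (by resampling) to the
    apical trunk; onsets ~ Normal(mean_onset, sigma_time).  Deterministic for
    a given seed.
    """
    if sigma_space_um < 0 or sigma_time_ms < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    trunk_len = (morph["apic_trunk0"].length + morph["apic_trunk1"].length)
    syns = []
    for _ in range(n_syn):
        pos = center_um + sigma_space_um * rng.standard_normal()
        while not 0.0 <= pos <= trunk_len:
            pos = center_um + sigma_space_um * rng.standard_normal()
        onset = mean_onset + sigma_time_ms * rng.standard_normal()
        syns.append(Exp2SynSpec(_apical(morph, pos), *INH_TAU, g_each_ns,
                                E_INH, onsets=(onset,)))
    return syns


def make_frequency_drive(freq_hz: float, duration_ms: float = 600.0,
                         amplitude_na: float = 0.3, pulse_ms: float = 2.0,
                         t0: float = 0.0) -> StimulusProtocol:
    """Periodic suprathreshold somatic steps driving 1:1 firing.

    Used for critical-frequency scans; the pulse shape (0.3 nA / 2 ms, as for
    single bAPs) is recorded in the protocol itself.
    """
    if freq_hz <= 0:
        raise ValueError("freq must be > 0")
    interval = 1000.0 / freq_hz
    events = [StepCurrentSpec(onset_ms=t0 + k * interval,
                              amplitude_na=amplitude_na,
                              duration_ms=pulse_ms)
              for k in range(int(math.ceil(duration_ms * freq_hz / 1000.0)))
              if t0 + k * interval < t0 + duration_ms]
    return StimulusProtocol(events, t_stim=t0)
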