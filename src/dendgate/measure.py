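"""Quantification of recordings: spikes, bAP amplitudes, calcium spikes,
and the three-way gating classification.

Amplitudes are maximum deviations from rest.  A somatic spike is an upward
crossing of rest + 80 mV (2 ms refractory).  The effect of inhibition on a
bAP is the test/control amplitude ratio at a dendritic probe; because the
transition is all-or-none, the ratio is bimodal and any mid-band threshold
separates the modes — 0.5 is used.  Calcium spikes are quantified by the
integral of the (inward) calcium current at the tuft probe, normalized to the
uninhibited integral; a ratio below 0.5 counts as canceled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .engine import Recording
from .morphology import Morphology, SiteAddress

__all__ = [
    "OutcomeClass",
    "standard_probes",
    "amplitude",
    "detect_spikes",
    "detect_somatic_spikes",
    "normalized_bap",
    "calcium_spike_magnitude",
    "classify_outcome",
]

SOMATIC_SPIKE_AMPLITUDE = 80.0   # mV above rest
REFRACTORY_MS = 2.0
BAP_CANCEL_THRESHOLD = 0.5       # normalized amplitude below this = canceled
CA_CANCEL_THRESHOLD = 0.5        # normalized Ca integral below this = canceled


class OutcomeClass(enum.Enum):
    """Trial outcome of dendritic inhibition during somatic firing."""

    BAP_INTACT = "bap_intact"
    BAP_CANCELED_SPIKE_INTACT = "bap_canceled_spike_intact"
    NO_SOMATIC_SPIKE = "no_somatic_spike"


def standard_probes(morph: Morphology) -> list:
    """The canonical probe set: basal 75 um, oblique 370 um, tuft 650 um
    (V and calcium current at the same spot), soma, and axon."""
    return [
        ("soma", SiteAddress("soma", 0.5), "V"),
        ("axon", SiteAddress("axon", 0.5), "V"),
        ("basal", morph.resolve_um("basal", 75.0), "V"),
        ("oblique", morph.resolve_um("oblique", 370.0), "V"),
        ("tuft", morph.resolve_um("apical", 650.0), "V"),
        ("tuft", morph.resolve_um("apical", 650.0), "I_Ca"),
        ("tuft", morph.resolve_um("apical", 650.0), "Ca"),
    ]


def amplitude(trace: np.ndarray, v_rest: float) -> float:
    """Maximum voltage deviation from rest (mV)."""
    trace = np.asarray(trace)
    if trace.size == 0:
        raise ValueError("empty trace")
    return float(np.max(trace) - v_rest)


def detect_spikes(t: np.ndarray, trace: np.ndarray, threshold: float,
                  refractory_ms: float = REFRACTORY_MS) -> np.ndarray:
    """Times of upward threshold crossings, separated by a refractory gap."""
    trace = np.asarray(trace)
    above = trace >= threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = []
    for i in idx:
        ti = t[i]
        if not times or ti - times[-1] >= refractory_ms:
            times.append(ti)
    return np.asarray(times)


def detect_somatic_spikes(t: np.ndarray, trace: np.ndarray, v_rest: float,
                          amplitude_mv: float = SOMATIC_SPIKE_AMPLITUDE
                          ) -> np.ndarray:
    """Somatic spike times: crossings of rest + 80 mV."""
    return detect_spikes(t, trace, v_rest + amplitude_mv)


def _rest(rec: Recording, label: str) -> float:
    return float(rec.get(label, "V")[0])


def normalized_bap(test: Recording, control: Recording, label: str,
                   window_ms: tuple | None = None) -> float:
    """Test/control amplitude ratio at a dendritic probe.

    The control amplitude is that of the first (uninhibited) bAP; with a
    burst in the control trace, ``window_ms`` can restrict the control
    amplitude to the first event.
    """
    tr_t, tr_c = test.get(label, "V"), control.get(label, "V")
    rest_t, rest_c = float(tr_t[0]), float(tr_c[0])
    if window_ms is not None:
        sel_c = (control.t >= window_ms[0]) & (control.t <= window_ms[1])
        sel_t = (test.t >= window_ms[0]) & (test.t <= window_ms[1])
    else:
        sel_c = np.ones_like(tr_c, dtype=bool)
        sel_t = np.ones_like(tr_t, dtype=bool)
    a_control = amplitude(tr_c[sel_c], rest_c)
    if a_control <= 0:
        raise ZeroDivisionError("control amplitude is zero")
    return amplitude(tr_t[sel_t], rest_t) / a_control


def calcium_spike_magnitude(test: Recording, control: Recording,
                            label: str = "tuft") -> float:
    """Ratio of integrated inward calcium current, test over control."""
    i_t = test.get(label, "I_Ca")
    i_c = control.get(label, "I_Ca")
    # inward calcium current is negative; integrate its magnitude
    q_t = float(np.trapezoid(np.clip(-i_t, 0.0, None), test.t))
    q_c = float(np.trapezoid(np.clip(-i_c, 0.0, None), control.t))
    if q_c <= 0:
        raise ZeroDivisionError("control calcium integral is zero")
    return q_t / q_c


def classify_outcome(test: Recording, control: Recording,
                     label: str = "oblique",
                     threshold: float = BAP_CANCEL_THRESHOLD,
                     window_ms: tuple | None = None) -> OutcomeClass:
    """Three-way classification of an inhibition trial.

    NO_SOMATIC_SPIKE if the somatic trace never reaches rest + 80 mV;
    otherwise BAP_CANCELED_SPIKE_INTACT if the normalized dendritic
    amplitude falls below ``threshold`` (default 0.5, inside the empty
    mid-band of the bimodal distribution); otherwise BAP_INTACT.
    """
    soma = test.get("soma", "V")
    spikes = detect_somatic_spikes(test.t, soma, float(soma[0]))
    if spikes.size == 0:
        return OutcomeClass.NO_SOMATIC_SPIKE
    ratio = normalized_bap(test, control, label, window_ms=window_ms)
    if ratio < threshold:
        return OutcomeClass.BAP_CANCELED_SPIKE_INTACT
    return OutcomeClass.BAP_INTACT
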