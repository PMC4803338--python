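# dendgate

**Inhibitory gating of dendritic coincidence signals — and therefore of
synaptic plasticity — in a pyramidal-neuron cable model.**

Hebbian plasticity at an excitatory synapse needs a postsynaptic coincidence
signal: the backpropagating action potential (bAP) at basal and oblique
synapses, or the distal calcium spike in the apical tuft. `dendgate` is a
self-contained conductance-based multi-compartment simulation of a simplified
cortical/hippocampal pyramidal cell built to ask when a shunting
(GABA_A-like) inhibitory synapse can *cancel* those signals without
destroying the forward-directed EPSP flow that drives somatic firing — in
other words, when inhibition can act as a binary switch for plasticity.

The package is aimed at computational neuroscientists who want a compact,
fully scriptable testbed for dendritic gating: every ingredient — morphology,
Hodgkin–Huxley channel kinetics with a distance-graded A-type K⁺ current, a
distal calcium-spike initiation zone, conductance synapses, an additive STDP
rule (Δw = −A₋e^{Δt/τ} for Δt ≤ 0, +A₊e^{−Δt/τ} for Δt > 0), and a two-cell
feedforward-inhibition circuit — is generated in-package, with no external
data.

Core phenomena it reproduces:

* **All-or-none bAP gating.** Over an inhibition-strength sweep the bAP
  amplitude in the oblique dendrite (normalized to the uninhibited trial)
  occupies two clusters, ≈1 and ≲0.3, with an empty mid band; the critical
  conductance at 90 µm from the soma is ≈25 nS.
* **Compartment specificity.** Proximal apical inhibition silences the whole
  apical tree but spares the basal bAP; basal inhibition does the reverse;
  distal inhibition cancels the calcium spike while bAPs survive.
* **Timing windows.** Cancelling the bAP (while keeping the somatic spike)
  requires millisecond-scale precision for proximal inhibition; distal
  calcium-spike gating tolerates a several-fold wider window.
* **STDP switching.** The classical asymmetric learning window at
  basal/oblique synapses, a non-negative window at the distal synapse (the
  calcium spike is the teacher there), and *identically flat* windows when
  the respective coincidence signal is inhibited.
* **Feedforward inhibition** provides exactly the ~2 ms
  excitation-to-inhibition delay the proximal gate requires — if the
  interneuron is fast; a slowed variant fails proximally but still gates the
  distal calcium spike.

## Worked example

```python
import numpy as np
import dendgate as dg

cell = dg.build_neuron()                    # calibrated default pyramidal cell
probes = dg.standard_probes(cell.morph)     # soma, axon, basal, oblique, tuft

# an uninhibited somatic threshold step: one spike, attenuating bAP
spec = dg.SimulationSpec(duration=50.0, probes=probes)
control = dg.simulate(cell, dg.make_somatic_step(t0=10.0), spec)

for g in (10.0, 30.0):
    proto = dg.make_somatic_step(t0=10.0)
    proto.add(dg.inhibitory_synapse(cell.morph, 90.0, g, onset=12.0))
    rec = dg.simulate(cell, proto, spec)
    ratio = dg.normalized_bap(rec, control, "oblique")
    outcome = dg.classify_outcome(rec, control, "oblique")
    print(f"{g:4.0f} nS at 90 um -> normalized bAP {ratio:.2f} ({outcome.value})")
```

```
  10 nS at 90 um -> normalized bAP 1.01 (bap_intact)
  30 nS at 90 um -> normalized bAP 0.14 (bap_canceled_spike_intact)
```

10 nS of shunting inhibition leaves the oblique bAP untouched; 30 nS —
just above the ≈25 nS critical conductance — removes it entirely while the
somatic spike still fires. That discontinuity is the plasticity switch.

Experiment drivers for every figure-level scan live in
`dendgate.experiments` and behind the CLI:

```bash
dendgate run fig3b --out results/   # strength x onset gating map, 90 um
dendgate run fig6  --out results/   # STDP windows with/without inhibition
dendgate params                     # full parameter table (YAML)
```

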