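# Model and methods

## The cell

`dendgate` implements a conductance-based multi-compartment model of a
pyramidal neuron with a deliberately simplified morphology: an axon initial
segment (2 × 3 µm), a cylindrical soma (18.5 × 18.5 µm), an apical trunk of
2 µm diameter and 500 µm total length split at the oblique junction
(100 µm + 400 µm), an oblique dendrite (300 µm) as the representative site of
one excitatory pathway, apical tuft branches beyond 500 µm, and a basal tree
(main shaft 1 µm × 150 µm). Daughter branches carry 2/3 of the diameter of
their mother; second-order branches exist purely to avoid sealed-end boundary
artifacts and carry no probes or synapses. The soma is a point in the path
metric, so "90 µm from the soma" means 90 µm of cable.

Passive properties: C_m = 0.75 µF/cm², R_a = 150 Ω·cm, R_m = 40 000 Ω·cm²,
E_L = −70 mV. Temperature is 30 °C (rate scales folded into the kinetic
constants).

## Channels

Six conductances in Hodgkin–Huxley form (`dendgate.channels`):

* transient Na (m³h), trap-form rates; activation shifted +5 mV in all
  dendrites (so distributed EPSPs drive somatic, not dendritic, spikes) and
  −10 mV in half of the axonal channels (0.6 S/cm² total in the axon,
  0.009 S/cm² elsewhere);
* delayed-rectifier K (n), 0.01 S/cm² everywhere;
* A-type K (n·l) with a density gradient: 0.029 S/cm² at the soma rising
  linearly five-fold over 500 µm and continuing along the tuft. The gradient
  is what attenuates the backpropagating action potential (bAP);
* high-voltage-activated Ca (m²h), 1.5·10⁻⁴ S/cm² in dendrites, ×2 at the
  soma, ×3 in the calcium zone;
* low-threshold Ca (m²h), 0.005 S/cm², only in the calcium-spike initiation
  zone (apical tuft, 500–750 µm path distance);
* Ca-activated K (one Hill-activated gate on the local calcium pool),
  2.5·10⁻⁴ S/cm² in dendrites, ×2 at the soma.

Reversals are fixed: E_Na = +60, E_K = −80, E_Ca = +140 mV. Each
calcium-carrying compartment has a submembrane calcium pool (shell depth
0.1 µm, resting 50 nM) filled by the local calcium current and relaxing with
τ = 100 ms.

The published models this channel family descends from do not pin every rate
constant, and the study's headline quantities are emergent, so the open
kinetic constants (collected in `KineticParams`) were calibrated **once**
against the benchmark behaviors of the modeled cell and then frozen:

* a single somatic spike for a threshold step (0.3 nA, 2 ms) peaking 2.5 ms
  after stimulus onset (the unprinted axon/soma threshold offset is set so
  0.3 nA is a true threshold stimulus);
* a bAP that propagates actively into the oblique dendrite (≈60% of the
  somatic amplitude at 370 µm) but arrives strongly attenuated in the tuft;
* an all-or-none collapse of the oblique bAP under proximal shunting
  inhibition with a critical conductance of ≈25 nS (90 µm, onset +2 ms);
* a distal calcium-spike ignition threshold of 8 nS for a coincident
  (Δt = 5 ms) synapse at 530 µm.

Two kinetic details deserve explicit mention because they are asymmetric in
time: recovery of A-type inactivation and of Na inactivation is faster than
the corresponding forward inactivation (`ka_ltau_rec`, `na_hrec_speedup`).
Without the fast Na recovery the cell cannot follow high-frequency somatic
drive 1:1, and summation at the calcium zone would *decrease* with drive
frequency.

## Numerics

The branched cable equation is integrated with a staggered backward-Euler
scheme at dt = 0.1 ms: gates advance by exponential Euler at the current
voltage; the voltage solve is a Hines elimination over the depth-first node
ordering (exact, unconditionally stable). Synaptic conductances enter the
implicit step as linear conductance terms evaluated at the step midpoint.
Initialization is V = −70 mV with gates at steady state, followed by 200 ms
of settling before t = 0 of any protocol. dt = 0.1 ms is coarse for action
potentials; the test suite therefore checks that halving dt changes bAP peak
amplitudes by <2% and flips no gating classification.

Discretization: nseg = 19/73 on the trunk compartments and 91 on every
branch (1550 nodes in total); a test verifies that somatic spike timing is
insensitive to doubling nseg at the stated discretization.

## Stimuli and synapses

Conductance synapses only. Double-exponential synapses are peak-normalized
(the stated maximum conductance *is* the peak): excitation τ = 0.5/2 ms,
E = 0 mV; shunting GABA_A-like inhibition τ = 0.5/5 ms, E = −73 mV (≈ rest,
so it shunts rather than hyperpolarizes). Plastic synapses are
single-exponential, τ = 3 ms. Protocols: the somatic threshold step (0.3 nA,
2 ms); BAC pairing (step + distal synapse at 530 µm); distributed trunk
excitation (8 synapses, 140–420 µm, 20 nS total, standing in for oblique
pathway input); inhibitory pulse trains; Gaussian-jittered inhibitory
populations (seeded; the only randomness in the package); and periodic
somatic drive for critical-frequency scans. For the frequency drive the pulse
amplitude is 0.5 nA (2 ms) rather than the threshold 0.3 nA: the scan
requires reliable 1:1 somatic firing up to 90 Hz, and a threshold-strength
pulse drops beats as soon as any adaptation accumulates. The pulse shape is
recorded in every protocol's metadata.

## Measures

Amplitudes are maximal deviations from rest; a somatic spike is an upward
crossing of rest + 80 mV (2 ms refractory). Inhibition trials are classified
three ways against an uninhibited control: somatic spike absent; somatic
spike present but the dendritic bAP canceled (normalized amplitude < 0.5);
or bAP intact. Because the transition is all-or-none, normalized amplitudes
are bimodal (clusters near 0–0.3 and 0.8–1.1) and any mid-band cutoff gives
the same classification; 0.5 is used and recorded in outputs. Calcium spikes
are quantified by the integrated inward calcium current at the tuft probe
(650 µm), normalized to the uninhibited integral; ratio < 0.5 counts as
canceled, justified by the same bimodality.

## Plasticity

Additive STDP (A₊ = 0.001, A₋ = 0.00106, τ± = 20 ms) with hard weight bounds
[0, 10⁻⁴ µS]. A± are read as fractions of the weight ceiling (the additive
convention): an absolute reading would traverse the entire printed weight
range in a single pairing, contradicting the 100-pairing protocol. The
plastic weight is a bookkeeping variable; trial dynamics use the stated
drive conductances (8 nS tuft, 0.001 nS basal/oblique — the tuft drive
exceeds the weight ceiling, so drive and weight cannot be one quantity).
Post events are −20 mV crossings at the synapse (basal/oblique) or the first
0.5 mM crossing of the distal calcium pool (tuft), where the calcium spike —
bimodally separated from sub-spike trials — governs plasticity. Pairing runs
100 times at 1 Hz; since all state relaxes between pairings, one trial is
simulated per offset and the weight update iterated with clipping. Windows
are normalized to the maximum absolute change of the uninhibited window of
the same synapse (a flat inhibited window is exact zeros, not 0/0). The
pairing offset axis is referenced to the somatic spike peak, so Δt ≈
t_post − t_pre as detected.

## Circuit

The feedforward-inhibition motif drives the pyramidal cell (8 trunk
synapses, 20 nS) and a single-compartment fast-spiking interneuron (300 nS
synapse; Na/K kinetics of the standard fast-spiking interneuron model, with
Na activation integrated as a state variable) from one source. The
interneuron's first spike triggers the 70 nS shunting synapse on the
pyramidal dendrite after a lumped 1.35 ms dead time (axonal conduction +
transmission); the resulting excitation→inhibition delays are 2.3 ms (fast
interneuron) and 2.65 ms (slow variant, Na activation opening scaled by 0.1
and closing by 0.2) — only the former falls inside the proximal cancel
window, while both fall inside the wide distal window. The
disinhibitory interneuron of the full motif is a boolean switch
(tonic disinhibition), not a third simulated cell.

## What the defaults do and do not show

The generator defaults are the study conditions: every scan in
`dendgate.experiments` (and `scripts/acceptance.py`) runs the default cell
with the stated protocol parameters. Passing tests show that *this* cell
expresses all-or-none bAP gating, compartment-specific cancellation, the
window-width asymmetry between bAP and calcium-spike control, STDP switching,
and FFI timing. They do not show robustness to morphological detail,
channel noise, in-vivo-like background input, or NMDA-dependent events —
all outside the model class.

Known limitations:

* The calcium-spike critical frequency of the default cell is ≈45–50 Hz,
  below the 80 Hz benchmark: once the frequency-dependent summation at the
  zone ignites at all, it does so well below 80 Hz. The all-or-none
  frequency nonlinearity itself is expressed; its location on the frequency
  axis is the least constrained emergent quantity of the kinetics
  re-implementation.
* The proximal bAP-cancellation window at 50 nS is ≈3 ms rather than ≈1 ms:
  the shunting conductance in this cell stays effective for a larger part of
  its decay. The qualitative ordering (narrow proximal bAP window, much
  wider distal calcium window, window width growing with distance from the
  soma) is reproduced.
* At the Δt = +5 ms pairing threshold the calcium event is small and does
  not drive a somatic burst; BAC-firing bursts require the coincident
  Δt = 0 protocol (the default BAC paradigm in the experiment drivers), and
  the distal-input-alone ignition threshold is ≈16 nS rather than 14 nS.
* Inhibition placed on the apical trunk distal to the oblique junction
  cannot, in a tree, gate the oblique bAP at all; window-versus-distance
  claims are therefore measured with the synapse on the soma-to-synapse
  path (inside the oblique branch beyond 100 um).
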