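# Model and methods

`ca3theta` simulates a scaled-down hippocampal circuit — an entorhinal
relay layer (EC, 30 cells), dentate gyrus (384 granule cells, 32 basket
cells, 32 HIPP interneurons) and CA3 (63 pyramidal cells, 8 basket cells,
8 OLM cells) — and asks how much each candidate theta (4–12 Hz) generator
contributes to the rhythm of the CA3 population when the only external
input is random Poisson spiking.

## Cell model

Every neuron is a two-variable quadratic integrate-and-fire (Izhikevich)
unit:

    C dv/dt = k (v − v_r)(v − v_t) − u + h + I
      du/dt = a (b (v − v_r) − u)
      if v ≥ v_peak:  v ← c,  u ← u + d,  h ← h + d_h

with per-type constants in `src/ca3theta/data/cells.yaml` (pyramidal cells:
C = 24 pF, k = 1.5, a = 0.01 ms⁻¹, b = 2, c = −63 mV, d = 60, v_r = −75 mV,
v_t = −58 mV, v_peak = 29 mV; granule, OLM and basket cells analogous).
The governing sign conventions are the standard stable ones: the printed
equation set we started from carries sign typos that would make rest a
repeller, so the canonical Izhikevich form is used.  Three points deserve
comment:

* **Adaptation is the theta clock.** After each spike `u` jumps by `d` and
  decays with τ = 1/a = 100 ms.  A pyramidal cell under sustained drive can
  therefore fire again preferentially after roughly that recovery time,
  which is the "spiking oscillation" at theta examined throughout.
  Raising `a` to 0.04 (τ = 25 ms) speeds the clock; `a` = 0.1 effectively
  removes it.
* **The h current** is a slow restorative current with first-order kinetics
  dh/dt = a_h(−b_h (v − v_r) − h) and an after-spike increment d_h,
  enabled for pyramidal and OLM cells only.  Its kinetic constants are
  fixed (a_h = 0.04/0.03 ms⁻¹, b_h = 10/3.5, d_h = 1), but its insertion
  gain in the voltage equation is not determined by the kinetics; we scale
  its contribution by `h_scale` = 0.15 (model.yaml) so that it adds
  subthreshold resonance without displacing the cells' rheobase.  Because
  h is linear, this is folded into effective b_h and d_h at catalog load.
* **OLM dynamic reset.** OLM/HIPP resets are state dependent — the reset
  rises and the cutoff falls with `u`.  Applied literally to `u` in pA
  the rule is unstable (d = 30 per spike would drive the cutoff below the
  reset within two spikes), so the coupling acts on u/C (mV/ms units) and
  is clamped at u/C = 1.5; this preserves the stereotyped OLM spike shape
  while keeping the map orderly under strong drive.

Slow currents (`u`, `h`) see the voltage capped at v_t, so the stereotyped
spike upstroke contributes a bounded, step-size-independent amount (the
after-spike increments `d`, `d_h` represent the spike's contribution).

EC relay cells are generic non-adapting spikers (b = 0) with a large,
fast-decaying after-spike current (d = 450, τ ≈ 14 ms) that spans exactly
one input event, so each Poisson input spike relays as one output spike
(~99% transmission at 15 Hz) and the layer carries no rhythm of its own.

## Synapses

Each connection class has a fast receptor (AMPA or GABA_A) and a slow one
(NMDA or GABA_B), both difference-of-exponentials with the published
rise/decay constants, delays, weights and short-term-plasticity kinds
(`data/synapses.yaml`).  Four modeling layers sit on top of the kinetics:

* **Driving force.** Currents are conductance-like: excitation is
  multiplied by (0 − v)/75 (unity at −75 mV), GABA_A by (v + 75)/20 and
  GABA_B by (v + 90)/35 (unity at −55 mV).  The ~25% sag of excitatory
  drive as a cell climbs toward threshold slows the effective adaptation
  clock the way a reversal potential would; GABA_A inhibition is shunting
  near rest and hyperpolarizing only for depolarized cells.
* **Saturating binding.** Arriving spikes drive a receptor channel's decay
  envelope toward an asymptote (g′ = g_max − (g_max − g) e^(−amount/g_max)),
  bounding the sustained current a pathway can deliver to one cell.  This
  is the discrete-event form of kinetic (two-state) receptor binding and
  is what compresses the lognormal drive: strongly driven cells sit at the
  ceiling and fire at the adaptation clock, weakly driven cells stay
  below threshold, and the population rate distribution remains
  right-skewed.  The global cap is 3.3 unit weights (132 pA); pathway
  overrides tune the operating point of each projection (e.g. 2.9 for
  EC→pyramidal, higher caps for interneuron drive because OLM cells need
  >176 pA sustained, none for the sub-millisecond kinetics where an
  envelope cap is meaningless and for the EC relay synapse).  With the cap
  set to `null` the kinetics are strictly linear and single-spike
  responses superpose exactly.
* **Slow excitatory summation.** External and entorhinal drive carries a
  slow NMDA-family component (25/300 ms) without the Mg block
  (`mg: false`), standing for the summating slow excitatory charge at
  depolarized spines; its pathway ratio is the knob that converts a
  50 Hz shot-noise train into quasi-tonic drive.  Recurrent and
  pyramidal→interneuron NMDA keeps the standard sigmoidal Mg block
  (evaluated at the postsynaptic cell's instantaneous voltage).
* **Charge normalization.** The pyramidal→interneuron AMPA kinetics are
  sub-millisecond; peak-normalized they would carry negligible charge, so
  those pathways carry a gain (2–2.5) chosen so a unitary event moves the
  postsynaptic cell by the ~1 mV seen in paired recordings.

Short-term plasticity is a single multiplicative factor per edge:
depressing pathways (recurrent, pyr→BC, BC→pyr, intra-DG analogues)
multiply a recovery variable by 0.7 per spike (τ = 300 ms recovery);
facilitating pathways (mossy, pyr→OLM) add 0.6/0.25 per spike (τ = 300/200
ms), capped at 4.  The per-spike gain is the factor at spike emission, so a
first pulse at rest always has gain 1.  Cholinergic state ACh ∈ [0, 2]
scales the fast-receptor increment by 1 + b_ACh (ACh − 1), clamped at 0;
the coefficients follow the published table (EC input −0.5, recurrent
−0.85, BC→pyr −0.5, mossy +0.49).  The table documents CA3-bound
projections, so the DG-bound perforant-path branch is left unmodulated.
The linear rule deliberately extrapolates below baseline (ACh = 0 gives
gain 1.5 at EC inputs).

## Network

Cells are placed uniformly in per-region 3-D boxes; the longitudinal axis
carries the lamellar organization, with each region's normalized
coordinate mapped onto a common 11.5 mm axis.  Published rules: EC→CA3/DG
Gaussian with peak 0.4 and σ = 3 mm; DG→CA3-BC 0.2/3 mm; mossy fibers
σ = 2 mm with exactly two pyramidal targets per granule cell; recurrent
fixed p = 0.3 (no self-connections); pyr→BC fixed 0.15; pyr→OLM is the
exact reciprocal of OLM→pyr.  The box length (the only free geometric
constant) and the unprinted OLM→pyr rule (peak 0.7, σ = 3 mm) were set
once so that the three published connectivity statistics hold: each EC
cell contacts ≈20% of CA3 pyramids, CA3 pyramidal pairs share ≈19% of
their EC sources and ≈32% of their OLM sources.  The pairwise overlap
statistic is |A∩B| / mean(|A|, |B|) (a Jaccard variant is available).
Per-edge weights are drawn Uniform(0.5 w, w).

## Inputs

All stimulus is synthetic: independent homogeneous Poisson trains, either
at 15 Hz per EC cell or directly to each pyramidal cell at per-cell rates
drawn from a lognormal distribution parameterized by its arithmetic mean
and SD (50 ± 40 Hz baseline; 20 ± 20 low ACh; 60 ± 50 high ACh).  The
direct-drive synapse reuses the EC→CA3 kinetics at lower weight; its
weight (0.85) and slow ratio (6.0) were calibrated once against the
isolated-cell condition and then frozen.

## Engine and numerics

The simulation is a fixed-step loop (dt = 0.1 ms) over flattened arrays,
JIT-compiled with numba.  Neuron updates use a midpoint (RK2) scheme with
adaptive sub-stepping (substeps sized so v moves ≤ ~2 mV each), which
keeps single-neuron spike times within ~0.05 ms per spike of a dt = 0.001
ms reference integration.  Receptor gating decays by exact exponential
factors; per-pathway constant delays are rounded to whole steps and
honored through FIFO queues; spike resets are simultaneous (v, u, h all
from pre-reset values).  Initial potentials are drawn Normal(v_r, 10 mV)
and clipped just below threshold so no cell starts mid-spike; u and h
start at 0.  All randomness flows from one master seed through named
substreams (positions, per-pathway connectivity, weights, initial
potentials, input trains), so seed-matched comparisons (e.g. with/without
DG) share everything except the manipulated component.  "Inactivating" a
population clamps it silent rather than deleting it; inactivating a
pathway removes its synapses; the five named theta generators map onto
these switches.  Runaway activity, queue overflow and non-finite states
abort with a cell/time diagnostic.

## Analysis conventions

Population spectra sum each type's spikes in 0.1 ms bins and Welch-average
with 1024 ms windows and 512 ms overlap (mean subtraction per window, no
taper; Hann available).  Peaks are the argmax of a ~2 Hz moving-average
smoothing within a stated band, ties resolving to the lower frequency.
Relative theta is the power sum over 4–12 Hz divided by 0–250 Hz.
Pairwise synchrony uses the Wang–Buzsáki measure at a 5 ms window; pairs
with a silent cell are skipped.  ISI modes come from 10-ms histograms of
pooled intervals.  Multi-seed experiments report mean ± SD over (default)
10 network instantiations; the DG-addition comparison uses a two-sided
paired t-test over seed-matched pairs (Wilcoxon reported alongside).

## What the generator emulates — and what it does not

The Poisson drive reproduces the *rates* of hippocampal afferents during
locomotion, deliberately without any rhythmic modulation, so every
spectral peak the model produces is generated inside the circuit or by
the divergence structure of its inputs.  Real afferents are
theta-modulated, correlated, and conductance-diverse; passing these tests
therefore demonstrates that the mechanisms *can* generate theta from
unstructured input at this scale, not that they quantitatively account
for in-vivo theta power.

## Known limitations

* The drive coupling (current-based with driving-force factors and
  saturating binding) reproduces the published rate calibrations and peak
  positions to within 1–2 Hz, but the ratio between spectral peak and
  pooled ISI mode differs from the source experiments: our isolated-cell
  ISI distributions are more symmetric (mode ≈ 1/peak), whereas the
  reported pair (8 Hz peak, 90 ms mode) implies strongly right-skewed
  intervals.  The pooled ISI modes in the isolated and strongly-coupled
  OLM conditions accordingly run ~50–70 ms long.
* In the basket-cell–pyramidal subnetwork, removing short-term depression
  and doubling connectivity raises basket-cell engagement but does not
  produce the robust emergent theta/beta peak reported for that ablation;
  the pyramidal rate under direct drive (≈3.5 Hz) appears too sparse for
  the PING-like coupling at this scale.
* The DG→CA3 contribution at high ACh is positive but small (~0.02
  relative theta) rather than ~0.15; with ~1 Hz granule-cell activity the
  mossy pathway carries too little rhythmic charge even with its +49%
  cholinergic enhancement.
* Spike counts proxy the LFP; there is no biophysical forward model, no
  long-term plasticity, no gap junctions, and no stochastic release.
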