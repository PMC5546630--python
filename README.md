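# ca3theta

A spiking-network model of intrinsic theta-rhythm (4–12 Hz) generation in
hippocampal CA3, for computational neuroscientists studying how circuit
mechanisms cooperate to produce population rhythms.  The model contains an
entorhinal relay layer (EC, 30 cells), a dentate gyrus (384 granule cells,
32 basket cells, 32 HIPP interneurons) and CA3 (63 pyramidal cells, 8
basket cells, 8 OLM interneurons), wired with lamellar Gaussian
connectivity in 3-D space and driven exclusively by random Poisson spikes
— so every rhythm it produces is made by the circuit, not imported with
the input.

Cells are Izhikevich-formulation point neurons,

    C dv/dt = k (v − v_r)(v − v_t) − u + h + I,
      du/dt = a (b (v − v_r) − u),     v ≥ v_peak ⇒ v ← c, u ← u + d,

whose after-spike recovery current `u` (τ = 1/a ≈ 100 ms for pyramids) is
the clock behind noise-induced "spiking oscillations" at theta.  Synapses
are kinetic AMPA/NMDA/GABA_A/GABA_B channels with published time
constants, delays and short-term plasticity (Varela-style depression and
facilitation), and a scalar cholinergic state ACh ∈ [0, 2] scales both
synaptic gains (via per-pathway b_ACh coefficients) and cellular
excitability.  Five candidate theta generators can be switched off
individually: the spiking oscillations themselves, the recurrent
collaterals, the OLM–pyramidal loop, the basket-cell loop, and the
divergent EC projection.  Analyses (Welch population spectra of 0.1 ms
spike counts, relative theta power, Wang–Buzsáki pairwise coherence,
spike-triggered averages, ISI histograms) live behind the same API.

See `docs/methods.md` for the full model description and its limitations.

## Worked example

Run the isolated-pyramid experiment (all synapses off, each cell driven by
its own lognormal-rate Poisson train) over 10 network instantiations:

```python
>>> from ca3theta import run_preset
>>> res = run_preset("fig4_isolated_pyr", master_seed=1, n_seeds=10)
>>> round(res["peak_hz"], 1), round(res["mean_rate_hz"], 2)
(5.9, 3.32)
```

The population spike-count spectrum of 63 *disconnected* cells shows a
broad theta-band peak: each cell prefers to fire again once its
adaptation current has decayed, so even independent cells share a
spectral timescale.  Replacing the cells' drive with divergent projections
from the non-rhythmic EC layer synchronizes those oscillations:

```python
>>> res = run_preset("fig5_ec_divergence", master_seed=1, n_seeds=10)
>>> round(res["peak_hz"], 1), round(res["mean_rate_hz"], 2)
(9.8, 7.67)
```

and the theta power rises far above the independent-cell case, even
though the EC spike trains themselves are Poisson.  The full circuit with
feedback inhibition and the dentate loop sits in between,

```python
>>> res = run_preset("fig3_full", master_seed=1, n_seeds=10)
>>> round(res["peak_hz"], 1), round(res["mean_rate_hz"], 2)
(6.8, 7.45)
```

with the mean pyramidal rate calibrated to the ~7 Hz place-cell average.
The numbered scripts under `analysis/` walk through the complete study —
single-cell properties, isolated-cell oscillations, EC divergence and the
lamellar-shuffle control, the recurrent and interneuron subnetworks, the
full model, and the cholinergic contribution sweep — writing tables under
`results/`.  A thin CLI mirrors the presets
(`ca3theta run fig3_full --seed 1 --n-seeds 10`).

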