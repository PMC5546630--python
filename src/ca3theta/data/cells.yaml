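# Izhikevich-formulation parameters per cell type.
# C pF; k unitless; a 1/ms; b unitless; c mV (after-spike reset); d (after-spike
# recovery increment); v_r, v_t, v_peak mV.  The slow restorative current h is
# enabled only for CA3 pyramidal and OLM/HIPP cells (a_h 1/ms, b_h unitless,
# d_h after-spike increment).
ca3_pyr:
  C: 24.0
  k: 1.5
  a: 0.01
  b: 2.0
  c: -63.0
  d: 60.0
  v_r: -75.0
  v_t: -58.0
  v_peak: 29.0
  h_enabled: true
  a_h: 0.04
  b_h: 10.0
  d_h: 1.0
# Variant used only for regressions of the burst response to brief pulses.
ca3_pyr_burst:
  C: 24.0
  k: 1.5
  a: 0.01
  b: 2.0
  c: -53.0
  d: 60.0
  v_r: -75.0
  v_t: -58.0
  v_peak: 29.0
  h_enabled: true
  a_h: 0.04
  b_h: 10.0
  d_h: 1.0
dg_gc:
  C: 24.0
  k: 1.0
  a: 0.015
  b: 3.0
  c: -62.0
  d: 3.0
  v_r: -73.0
  v_t: -53.0
  v_peak: 32.0
olm:
  C: 80.0
  k: 1.5
  a: 0.003
  b: 10.0
  c: -65.0
  d: 30.0
  v_r: -68.0
  v_t: -53.0
  v_peak: 30.0
  h_enabled: true
  a_h: 0.03
  b_h: 3.5
  d_h: 1.0
  # reset depends on u: c_eff = c + 10*u, v_peak_eff = v_peak - 30*u
  olm_dynamic_reset: true
bc:
  C: 16.0
  k: 1.5
  a: 0.9
  b: 2.0
  c: -80.0
  d: 400.0
  v_r: -65.0
  v_t: -50.0
  v_peak: 28.0
# Generic non-adapting spiking cells for the entorhinal input layer: b = 0
# and a fast-decaying after-spike current (large d, 14 ms recovery) give a
# brief refractory period spanning one synaptic event, so each input spike
# relays as one output spike with no adaptation across events.
ec:
  C: 24.0
  k: 1.5
  a: 0.07
  b: 0.0
  c: -70.0
  d: 450.0
  v_r: -70.0
  v_t: -55.0
  v_peak: 30.0
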