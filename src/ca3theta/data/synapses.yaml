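# Connection-class (pathway) catalog: kinetics, delays, weights, cholinergic
# coefficients (b_ach on the fast/AMPA component only) and short-term
# plasticity kind.  Time constants in ms, weights unitless (scaled globally
# by model.current_scale into pA at the synapse).
#
# slow_kind: nmda (voltage-dependent Mg block), gabab (slow linear inhibition)
# stp: none | depressing (per-spike factor stp_f, recovery stp_tau)
#            | facilitating (per-spike increment stp_f, recovery stp_tau)
pathways:
  ec_pyr:
    src: ec
    tgt: ca3_pyr
    sign: 1
    fast: {rise: 1.7, decay: 10.9}
    slow: {rise: 25.0, decay: 300.0, kind: nmda, mg: false, ratio: 1.5}
    delay: 5.0
    weight: 2.0
    b_ach: -0.5
    stp: {kind: none}
    saturation: 3.45
  ec_bc:
    src: ec
    tgt: ca3_bc
    sign: 1
    fast: {rise: 1.7, decay: 10.9}
    slow: {rise: 25.0, decay: 300.0, kind: nmda, mg: false, ratio: 1.5}
    delay: 5.0
    weight: 2.0
    b_ach: -0.5
    stp: {kind: none}
    saturation: 2.1
  ec_gc:
    src: ec
    tgt: dg_gc
    sign: 1
    fast: {rise: 1.7, decay: 10.9}
    slow: {rise: 25.0, decay: 300.0, kind: nmda, mg: false, ratio: 1.5}
    delay: 5.0
    weight: 2.0
    # cholinergic suppression is documented for the CA3-bound perforant
    # path; the DG-bound branch is left unmodulated
    b_ach: 0.0
    stp: {kind: none}
    saturation: 3.0
  ec_dgbc:
    src: ec
    tgt: dg_bc
    sign: 1
    fast: {rise: 1.7, decay: 10.9}
    slow: {rise: 25.0, decay: 300.0, kind: nmda, mg: false, ratio: 1.5}
    delay: 5.0
    weight: 2.0
    b_ach: 0.0
    stp: {kind: none}
    saturation: 2.4
  # Mossy fibers: fastest AMPA onto CA3 pyramids, pronounced facilitation,
  # cholinergic enhancement (+49% at high ACh).
  mossy:
    src: dg_gc
    tgt: ca3_pyr
    sign: 1
    fast: {rise: 0.5, decay: 4.0}
    slow: {rise: 25.0, decay: 300.0, kind: nmda}
    delay: 1.5
    weight: 6.0
    b_ach: 0.49
    stp: {kind: facilitating, f: 0.6, tau: 300.0}
    saturation: 6.0
  dg_bc:
    src: dg_gc
    tgt: ca3_bc
    sign: 1
    fast: {rise: 1.1, decay: 5.0}
    slow: {rise: 25.0, decay: 300.0, kind: nmda}
    delay: 1.5
    weight: 2.0
    b_ach: 0.0
    stp: {kind: none}
  rc:
    src: ca3_pyr
    tgt: ca3_pyr
    sign: 1
    fast: {rise: 1.1, decay: 5.0}
    slow: {rise: 25.0, decay: 300.0, kind: nmda}
    delay: 2.0
    weight: 0.4
    b_ach: -0.85
    stp: {kind: depressing, f: 0.7, tau: 300.0}
  pyr_olm:
    src: ca3_pyr
    tgt: ca3_olm
    sign: 1
    fast: {rise: 0.27, decay: 0.57}
    slow: {rise: 25.0, decay: 150.0, kind: nmda, mg: false, ratio: 0.3}
    delay: 0.9
    weight: 3.0
    b_ach: 0.0
    stp: {kind: facilitating, f: 0.25, tau: 200.0}
    # slow-channel cap sized so OLM recruitment tracks the pathway weight
    # scale; the sub-ms fast channel is left linear
    saturation: 3.0
    saturation_fast: null
    # brief kinetics are charge-normalized so a unitary event moves the
    # postsynaptic cell by ~1 mV, as in paired recordings
    gain: 2.0
  pyr_bc:
    src: ca3_pyr
    tgt: ca3_bc
    sign: 1
    fast: {rise: 0.27, decay: 0.57}
    slow: {rise: 25.0, decay: 150.0, kind: nmda}
    delay: 0.9
    weight: 3.0
    b_ach: 0.0
    stp: {kind: depressing, f: 0.7, tau: 300.0}
    saturation: null
    gain: 2.5
  olm_pyr:
    src: ca3_olm
    tgt: ca3_pyr
    sign: -1
    fast: {rise: 2.8, decay: 20.8}
    slow: {rise: 11.1, decay: 125.0, kind: gabab}
    delay: 0.8
    weight: 3.0
    b_ach: 0.0
    stp: {kind: none}
    # dendritic inhibition paces rather than silences the pyramids
    saturation: 1.0
  bc_pyr:
    src: ca3_bc
    tgt: ca3_pyr
    sign: -1
    fast: {rise: 0.21, decay: 3.3}
    slow: {rise: 11.1, decay: 125.0, kind: gabab}
    delay: 0.8
    weight: 3.0
    b_ach: -0.5
    stp: {kind: depressing, f: 0.7, tau: 300.0}
    saturation: 3.0
  bc_olm:
    src: ca3_bc
    tgt: ca3_olm
    sign: -1
    fast: {rise: 0.21, decay: 3.3}
    slow: {rise: 11.1, decay: 125.0, kind: gabab}
    delay: 0.8
    weight: 3.0
    b_ach: -0.5
    stp: {kind: depressing, f: 0.7, tau: 300.0}
  # Intra-DG classes mirror their CA3 analogues; weights tuned for sparse
  # granule-cell firing.
  gc_dgbc:
    src: dg_gc
    tgt: dg_bc
    sign: 1
    fast: {rise: 0.27, decay: 0.57}
    slow: {rise: 25.0, decay: 150.0, kind: nmda}
    delay: 0.9
    weight: 3.0
    b_ach: 0.0
    stp: {kind: depressing, f: 0.7, tau: 300.0}
  dgbc_gc:
    src: dg_bc
    tgt: dg_gc
    sign: -1
    fast: {rise: 0.21, decay: 3.3}
    slow: {rise: 11.1, decay: 125.0, kind: gabab}
    delay: 0.8
    weight: 3.0
    b_ach: -0.5
    stp: {kind: depressing, f: 0.7, tau: 300.0}
  gc_hipp:
    src: dg_gc
    tgt: dg_hipp
    sign: 1
    fast: {rise: 0.27, decay: 0.57}
    slow: {rise: 25.0, decay: 150.0, kind: nmda, mg: false, ratio: 0.5}
    delay: 0.9
    weight: 3.0
    b_ach: 0.0
    stp: {kind: facilitating, f: 0.25, tau: 200.0}
  hipp_gc:
    src: dg_hipp
    tgt: dg_gc
    sign: -1
    fast: {rise: 2.8, decay: 20.8}
    slow: {rise: 11.1, decay: 125.0, kind: gabab}
    delay: 0.8
    weight: 3.0
    b_ach: 0.0
    stp: {kind: none}
  # External Poisson drive synapses (AMPA + NMDA).  ext_ec is strong enough
  # for ~100% spike transmission; ext_pyr is the lower-weight direct drive
  # with parameters matching the EC -> CA3 synapses.
  ext_ec:
    src: ext
    tgt: ec
    sign: 1
    fast: {rise: 1.7, decay: 10.9}
    slow: {rise: 25.0, decay: 300.0, kind: nmda}
    delay: 1.0
    weight: 10.0
    b_ach: 0.0
    stp: {kind: none}
    # relay synapse: strong and unsaturated so every input spike transmits
    saturation: null
  ext_pyr:
    src: ext
    tgt: ca3_pyr
    sign: 1
    fast: {rise: 1.7, decay: 10.9}
    # slow excitatory summation component: NMDA-family kinetics carried
    # without the Mg block (lumped depolarized-spine drive), pathway ratio
    slow: {rise: 25.0, decay: 300.0, kind: nmda, mg: false, ratio: 6.0}
    delay: 1.0
    weight: 0.85
    b_ach: -0.5
    stp: {kind: none}
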