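# Global model constants: unit scaling, receptor composition, initial
# conditions, and cholinergic neuronal-effect magnitudes.
#
# current_scale converts the unitless catalog weights into peak synaptic
# current (pA); it is the single global calibration constant, fixed so the
# EC-driven baseline network yields a mean CA3 pyramidal rate of ~7 Hz
# (the in-vivo place-cell calibration).
current_scale: 40.0

# Peak amplitude of the slow receptor component relative to the fast one.
nmda_ratio: 0.3
gabab_ratio: 0.1

# Sigmoidal magnesium-block parameters for NMDA: B(v) = 1/(1+exp(-slope*v)/k)
mg_block: {slope: 0.062, k: 3.57}

# Per-edge weights are drawn Uniform(jitter_lo*w, jitter_hi*w).
weight_jitter: [0.5, 1.0]

# Initial membrane potentials ~ Normal(v_r, init_v_sd); u and h start at 0.
init_v_sd: 10.0

# Facilitation gain cap (running STP gain stays in (0, stp_f_max]).
stp_f_max: 4.0

# Cholinergic effects on neurons, linear in (ACh - 1).  Magnitudes are model
# constants (directions are the constrained quantity): v_r shifts in
# mV per ACh unit; pyr burstiness lowers c (mV) and d; olm_adaptation scales
# the adaptation strength (b and d) by (1 + slope*(ACh-1)), floored at 0.1.
ach_effects:
  pyr_depolarize: {dv_r: 2.0}
  pyr_burstiness: {dc: -4.0, dd: -15.0}
  olm_depolarize: {dv_r: 3.0}
  olm_adaptation: {slope: -0.3}
  bc_depolarize: {dv_r: 1.0}

# Saturating receptor binding: each arriving spike drives the channel's
# decay envelope toward an asymptote of saturation_cap unit weights
# (g' = gmax - (gmax - g) exp(-amount/gmax)), bounding the sustained
# synaptic current per pathway and postsynaptic cell.  Set to null for
# strictly linear (superposing) kinetics.
saturation_cap: 3.3

# Coupling scale of the slow restorative h current in the voltage equation
# (the kinetics follow the cell catalog; the insertion gain is a model
# constant chosen to keep the rheobase shift moderate while preserving
# subthreshold resonance).  h is linear, so this scales b_h and d_h.
h_scale: 0.15
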