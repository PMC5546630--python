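# Region geometry and spatially structured connection rules.
#
# Each region is a 3-D box (mm).  The longitudinal (first) axis carries the
# lamellar organization: connection probability between regions depends on
# the distance between the *normalized* longitudinal coordinates of the two
# cells, mapped onto the 11.5 mm CA3/DG axis.
regions:
  ec:
    box: [11.5, 0.5, 0.5]
    counts: {ec: 30}
  dg:
    box: [11.5, 0.5, 0.5]
    counts: {dg_gc: 384, dg_bc: 32, dg_hipp: 32}
  ca3:
    box: [11.5, 0.5, 0.5]
    counts: {ca3_pyr: 63, ca3_bc: 8, ca3_olm: 8}

# Connection rules, one per pathway in synapses.yaml.
# kinds: gaussian (peak prob p at distance 0, s.d. sigma mm along the
#        longitudinal axis), fixed (uniform probability p),
#        gaussian_capped (exactly `cap` targets sampled with Gaussian weights,
#        used for the sparse mossy fibers), reciprocal (reverse every edge of
#        pathway `of`).
rules:
  ec_pyr:   {kind: gaussian, p: 0.4, sigma: 3.0}
  ec_bc:    {kind: gaussian, p: 0.4, sigma: 3.0}
  ec_gc:    {kind: gaussian, p: 0.4, sigma: 3.0}
  ec_dgbc:  {kind: gaussian, p: 0.4, sigma: 3.0}
  mossy:    {kind: gaussian_capped, sigma: 2.0, cap: 2}
  dg_bc:    {kind: gaussian, p: 0.2, sigma: 3.0}
  rc:       {kind: fixed, p: 0.3, self: false}
  pyr_olm:  {kind: reciprocal, of: olm_pyr}
  pyr_bc:   {kind: fixed, p: 0.15}
  olm_pyr:  {kind: gaussian, p: 0.7, sigma: 3.0}
  bc_pyr:   {kind: gaussian, p: 0.3, sigma: 3.0}
  bc_olm:   {kind: gaussian, p: 0.3, sigma: 3.0}
  gc_dgbc:  {kind: fixed, p: 0.15}
  dgbc_gc:  {kind: gaussian, p: 0.3, sigma: 3.0}
  gc_hipp:  {kind: reciprocal, of: hipp_gc}
  hipp_gc:  {kind: gaussian, p: 0.7, sigma: 3.0}
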