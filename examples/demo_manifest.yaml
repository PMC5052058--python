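# End-to-end demo: simulate wild-type and rad16-null CPD repair plus Abf1
# binding, normalize, compute repair rates, detect sites, build composite
# profiles and quantify the GG-NER-dependent repair domain.
seed: 11
output_dir: demo_output
steps:
  - step: simulate
    name: sim
    spec:
      chrom_lengths: [[chrI, 300000], [chrII, 200000]]
    repair:
      scenarios: [wildtype, rad16_null]
    binding:
      uv_states: [pre]
  - step: normalize
    name: wt_t0
    input: sim.cpd.wildtype.t0
    mode: quantile_only
  - step: normalize
    name: wt_t120
    input: sim.cpd.wildtype.t120
    mode: quantile_only
  - step: normalize
    name: mut_t0
    input: sim.cpd.rad16_null.t0
    mode: quantile_only
  - step: normalize
    name: mut_t120
    input: sim.cpd.rad16_null.t120
    mode: quantile_only
  - step: repair_rate
    name: rate_wt
    t0: wt_t0
    t_repair: wt_t120
  - step: repair_rate
    name: rate_mut
    t0: mut_t0
    t_repair: mut_t120
  - step: detect
    name: abf1_sites
    input: sim.binding.pre
  - step: profile
    name: prof_wt
    mode: point
    track: rate_wt
    features: abf1_sites
  - step: profile
    name: prof_mut
    mode: point
    track: rate_mut
    features: abf1_sites
  - step: difference
    name: gg_deficit
    p1: prof_wt
    p2: prof_mut
  - step: domain
    name: gg_domain
    input: gg_deficit
  - step: localize
    name: site_positions
    sites: abf1_sites
    genes: sim.genes
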