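# Built-in condition presets: diet x host-genotype parameter bundles for the
# heteroplasmy life-cycle simulator. All values are phenomenological
# calibrations (directions from the underlying experiments, magnitudes chosen
# so that the wildtype live-food preset reproduces the documented behavior:
# parent->adult shift zero-crossing at 77.5% and non-competing populations
# stable near 60%). The cost-ramp shape (ramp width 0.02,
# cost 0.95, delay slope 1.2) was fixed by grid search against that
# stability target with theta pinned at the 0.60 phenotype boundary.
presets:
  # live E. coli diet, wildtype nuclear background (the reference condition)
  wt_live:
    delta_embryo: -0.03
    shift_a: 0.179
    shift_b: -0.20
    shift_sd: 0.03
    wt_setpoint: 200000
    fecundity_base: 5.0
    fecundity_theta: 0.60
    fecundity_cost: 0.95
    fecundity_ramp: 0.02
    delay_slope: 1.2
    f_max: 0.90
    bottleneck_b: 200
  # UV-killed control (plentiful) diet, wildtype background
  wt_control:
    delta_embryo: -0.03
    shift_a: 0.125
    shift_b: -0.15
    shift_sd: 0.03
    wt_setpoint: 180000
    fecundity_base: 4.0
    fecundity_theta: 0.60
    fecundity_cost: 0.95
    fecundity_ramp: 0.02
    delay_slope: 1.2
    f_max: 0.90
    bottleneck_b: 200
  # UV-killed restricted diet (100-fold diluted lawn), wildtype background:
  # the parent->embryo purifying shift vanishes and the developmental gain
  # is nearly abolished
  wt_restricted:
    delta_embryo: 0.0
    shift_a: 0.008
    shift_b: -0.01
    shift_sd: 0.03
    wt_setpoint: 140000
    fecundity_base: 2.0
    fecundity_theta: 0.60
    fecundity_cost: 0.95
    fecundity_ramp: 0.02
    delay_slope: 1.2
    f_max: 0.90
    bottleneck_b: 200
  # daf-16(mu86) null, control diet: mutant gain requires DAF-16, so the
  # within-host advantage is largely lost
  daf16_control:
    delta_embryo: -0.02
    shift_a: 0.066
    shift_b: -0.08
    shift_sd: 0.03
    wt_setpoint: 180000
    fecundity_base: 4.0
    fecundity_theta: 0.60
    fecundity_cost: 0.95
    fecundity_ramp: 0.02
    delay_slope: 1.2
    f_max: 0.90
    bottleneck_b: 200
  # daf-16 null under diet restriction: net within-host dynamics slightly
  # negative and the host cost of heteroplasmy intensified (DAF-16 normally
  # buffers organismal selection during scarcity)
  daf16_restricted:
    delta_embryo: 0.0
    shift_a: -0.02
    shift_b: -0.05
    shift_sd: 0.03
    wt_setpoint: 140000
    fecundity_base: 2.0
    fecundity_theta: 0.60
    fecundity_cost: 0.98
    fecundity_ramp: 0.02
    delay_slope: 1.6
    f_max: 0.90
    bottleneck_b: 200
  # daf-2(e1370) insulin-receptor mutant: reduced germline mtDNA biogenesis,
  # reduced mutant gain, lowered copy-number setpoint
  daf2:
    delta_embryo: -0.03
    shift_a: 0.02
    shift_b: -0.10
    shift_sd: 0.03
    wt_setpoint: 120000
    fecundity_base: 4.0
    fecundity_theta: 0.60
    fecundity_cost: 0.95
    fecundity_ramp: 0.02
    delay_slope: 1.2
    f_max: 0.90
    bottleneck_b: 200
  # daf-2; daf-16 double mutant: loss of DAF-16 restores biogenesis and the
  # mutant's within-host advantage
  daf2_daf16:
    delta_embryo: -0.03
    shift_a: 0.15
    shift_b: -0.18
    shift_sd: 0.03
    wt_setpoint: 190000
    fecundity_base: 4.5
    fecundity_theta: 0.60
    fecundity_cost: 0.95
    fecundity_ramp: 0.02
    delay_slope: 1.2
    f_max: 0.90
    bottleneck_b: 200

# Bacterial lawn concentrations used for the UV-killed diet design
# (cells per mL of seeding suspension).
diet:
  control_cells_per_ml: 2.0e+10
  restricted_cells_per_ml: 2.0e+8

# Lysate dilution factors used ahead of droplet generation, by sample type.
ddpcr_dilutions:
  embryos: 20
  pooled_larvae: 200
  single_adult: 200
  pooled_adults: 1000
  competition_pool_control: 20000
  competition_pool_restricted: 2000
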