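# Packaged default profile: every kinetic constant pinned to a measured
# anchor point of the surface nucleation assay.
kinetics:
  k_ref: 9.282484858415345e-06   # -ln(1 - 0.005)/540 s: 0.5% fire in 9 min at c_ref
  c_ref: 20.0                    # uM
  n_coop: 6.7                    # cooperativity exponent
  v_slope: 2.0615384615384618    # 26.8/13 nm/s/uM: 26.8 nm/s at 15 uM (seed)
  c_elong: 2.0                   # uM, plus-end elongation threshold
  turc_speed_factor: 0.9813432835820896   # 26.3/26.8
  v_minus_slope: 0.5384615384615384       # 7.0/13: 7.0 nm/s at 15 uM (seed minus end)
  c_elong_minus: 2.0
  speed_sd_plus: 4.2             # nm/s between-filament SD
  speed_sd_minus: 2.2            # nm/s
  k_spont_ref: 0.016647868719199307  # 2/(1200*0.75^8): detection first passes at 15 uM
  n_spont: 8.0
assay:
  assay: gturc
  tubulin_conc: 15.0
  n_templates: 130000            # calibrated: templated detection first passes at 7.5 uM
  field_size: [164.0, 164.0]     # um
  duration: 1200.0               # s
  frame_interval: 5.0            # s
  dose:
    map_kind: none
    concentration: 0.0
seed: 1
write_trajectories: true
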