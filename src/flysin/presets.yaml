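# Genotype presets for the synthetic fly-group simulator.
#
# active_social emulates a normally active, socially engaged wild-type-like
# group: fast, fairly straight walking with brief engagement holds, so most
# contacts come from high traffic past many distinct partners.
# hypoactive_asocial emulates a hypoactive strain: slower, more tortuous
# walking with frequent pauses and a much longer dwell per engagement, so it
# accumulates fewer, longer interactions and a sparser network, plus a
# slightly stronger boundary preference.
#
# Magnitudes were calibrated once so the full pipeline recovers the
# directional group phenotype (activity, connectivity, duration-strength,
# heterogeneity, betweenness, modularity) on scaled-down recordings; see
# docs/methods.md.
active_social:
  n_flies: 30
  duration_s: 900.0
  fps: 60.0
  mean_speed: 14.0
  speed_sd: 2.0
  heading_noise_sd: 7.0
  pause_prob: 0.005
  pause_mean_s: 0.5
  wall_bias: 0.55
  social_radius: 10.0
  social_strength: 0.35
  interaction_hold_s: 0.5
  body_length_mean: 2.5
  body_length_sd: 0.2

hypoactive_asocial:
  n_flies: 30
  duration_s: 900.0
  fps: 60.0
  mean_speed: 7.0
  speed_sd: 1.5
  heading_noise_sd: 12.0
  pause_prob: 0.035
  pause_mean_s: 1.5
  wall_bias: 0.75
  social_radius: 10.0
  social_strength: 0.3
  interaction_hold_s: 7.0
  body_length_mean: 2.5
  body_length_sd: 0.2
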