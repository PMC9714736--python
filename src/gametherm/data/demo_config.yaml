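breadth_threshold: 0.8
e0_per_ul: 0.02
egg_diameter_um: 130.0
exposure_time_s: 900.0
frame_rate_hz: 60.0
motility_threshold_um_s: 5.0
n_tracks: 20
output_dir: gametherm_demo
s0_per_ul: 0.45454545454545453
seed: 0
species: sand_dollar
stages:
  art_anova: true
  fertkin: true
  fit_tpc: true
  kinematics: true
  simulate: true
tpc_ci_level: 0.95
tpc_models:
- quadratic
- gaussian
- modifiedgaussian
tpc_n_boot: 200
tpc_n_starts: 8
track_duration_s: 10.0
track_radius_um: 50.0
track_speed_um_s: 300.0
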