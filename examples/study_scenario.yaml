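# Deployment-shaped default scenario: 6 animal-mounted, 5 indoor and 6
# outdoor static trackers, 7 days, GPS every 15 min, motion counts every
# minute.  Static GPS error calibrated to 95% containment radii of 15 m
# (outdoor) and 40 m (indoor).
pipeline:
  z_threshold: 4.5
  utm_zone: 13
  # calendar-day boundary; the study site would be America/Denver
  day_timezone: UTC
  min_fixes_per_day: 2

scenario:
  n_animal: 6
  n_indoor: 5
  n_outdoor: 6
  outdoor_r95_m: 15.0
  indoor_r95_m: 40.0
  outlier_prob: 0.0005
  outlier_min_m: 5000.0
  outlier_max_m: 500000.0
  site_lat: 36.45
  site_lon: -103.15
  utm_zone: 13
  rng_seed: 1
  movement:
    p_rest_to_active: 0.02
    p_active_to_rest: 0.0425
    step_mean_m: 6.0
    step_shape: 4.0
    turn_kappa: 8.0
    mi_mean: 3.0
  schedule:
    gps_interval_min: 15
    motion_interval_min: 1
    days: 7
    fix_dropout_prob: 0.1
    start: "2020-12-25"

alpha: 0.05
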