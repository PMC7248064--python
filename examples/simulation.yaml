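# Synthetic survey campaign: two lek-breeding and one explosive taxon on
# five 25 km² plots, three surveys per season over two years.
n_plots: 5
plot_area_km2: 25.0
seed: 42
mean_small: 14.0
mean_medium: 2.5
mean_large: 0.5
mean_ditch: 5.0
surveyed_fraction:
  small: 0.27
  medium: 0.49
  large: 0.57
  ditch: 0.5
years: [2016, 2017]
onset_day_of_year: 97
survey_rel_days: [5.0, 14.0, 23.0]
survey_rel_daytimes: [0.4, 0.6, 0.9]
site_fidelity: 0.8
visual_coverage: 0.8
taxa:
  lek-frog:
    density: 30.0
    ma: 0.63
    mp: 1.0
    ms: 0.47
    ms_large: 0.36
    hearing_distance_m: 500
    breeding_profile: lek
    peak_day: 14.0
    season_width_days: 15.0
  explosive-frog:
    density: 40.0
    ma: 0.3
    mp: 0.95
    ms: 0.48
    hearing_distance_m: 50
    breeding_profile: explosive
    peak_day: 8.0
    season_width_days: 6.0
    site_peak_jitter_days: 5.0
  night-caller:
    density: 25.0
    ma: 0.58
    mp: 0.72
    ms: 0.55
    hearing_distance_m: 500
    nocturnal: true
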