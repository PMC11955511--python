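# Full-pipeline configuration: synthetic assemblage at the default study
# conditions, then space, activity, and network stages.
synthetic:
  seed: 7
  n_interactions: 33
  conspecific_bias: 4.0
  behavior_mix: {looking: 0.3939393939393939, courtship: 0.4242424242424242,
                 aggression: 0.12121212121212122, other: 0.06060606060606061}
  species:
    calcaratus:
      n_females: 9
      n_males: 21
      home_center: [0.0, 0.0]
      home_sd: 2.5
      phenology_peak: 128
      phenology_sd: 15
      sun_preference: 0.94
    coecatus:
      n_females: 21
      n_males: 14
      home_center: [4.0, 2.0]
      home_sd: 2.7
      phenology_peak: 176
      phenology_sd: 15
      sun_preference: 0.60
    decorus:
      n_females: 21
      n_males: 13
      home_center: [2.0, -2.0]
      home_sd: 8.0
      phenology_peak: 152
      phenology_sd: 45
      sun_preference: 0.33
    orbus:
      n_females: 9
      n_males: 0
      home_center: [-3.0, 3.0]
      home_sd: 3.0
      phenology_peak: 160
      phenology_sd: 45
      sun_preference: 0.50

space:
  group: species
  levels: [50, 95]
  grid_cells: 200
  bandwidth: href

activity:
  span: 0.75

network:
  behaviors: [all, courtship]
  n_perm: 10000
  seed_base: 1
  direction: less
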