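# Demonstration configuration: 15-species synthetic forest with two
# aggregation guilds, planted segregation, and guild signal, at
# Monte-Carlo sizes that finish in a few minutes on one CPU.
root_depth: 1000
soil_depth: 1100
cutoffs:
- 0.3
- 0.5
- 0.7
- 0.9
mra_cutoffs:
- 0.5
n_perm: 199
n_sim_envelopes: 99
n_rep: 10
n_trees: 100
simulation:
  window_width_m: 1000.0
  window_height_m: 500.0
  n_species: 15
  individuals_per_species: 80
  parents_per_species: 18
  cluster_sd_m: 12.0
  hardcore_dist_m: 50.0
  pair_relationships:
    0-1: aggregated
    0-2: aggregated
    0-3: aggregated
    0-4: aggregated
    0-5: aggregated
    1-2: aggregated
    1-3: aggregated
    1-4: aggregated
    1-5: aggregated
    2-3: aggregated
    2-4: aggregated
    2-5: aggregated
    3-4: aggregated
    3-5: aggregated
    4-5: aggregated
    6-7: aggregated
    6-8: aggregated
    6-9: aggregated
    6-10: aggregated
    6-11: aggregated
    7-8: aggregated
    7-9: aggregated
    7-10: aggregated
    7-11: aggregated
    8-9: aggregated
    8-10: aggregated
    8-11: aggregated
    9-10: aggregated
    9-11: aggregated
    10-11: aggregated
    0-12: segregated
    1-13: segregated
    2-14: segregated
    3-12: segregated
    4-13: segregated
    5-14: segregated
    6-12: segregated
    7-13: segregated
    8-14: segregated
    9-12: segregated
    10-13: segregated
    11-14: segregated
  host_effect: 5.0
  guild_signal: 4.0
  n_otus: 600
  root_depth: 1000
  soil_depth: 1100
  samples_per_species: 8
  n_soil_samples: 60
  pathogen_fraction: 0.1
  ecm_fraction: 0.14
  saprotroph_fraction: 0.2
  dbh_meanlog: 1.5
  dbh_sdlog: 0.8
  env_range_m: 150.0
  env_sill: 1.0
  env_nugget: 0.0
  env_grid_m: 25.0
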