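# Full-pipeline configuration: simulate a study and run every stage.
#   gorillanet --config examples/config.yaml --outdir out all
# Replace `simulate: true` with `simulate: false` plus a `paths:` block to
# run on your own tables.
simulate: true
seed: 1
scenario:
  n_groups: 3
  years: 8
  females_per_group: [2, 7]
  focals_per_female_year: [100.0, 50.0]
  scans_per_focal: [2, 6]
  birth_rate: 0.2
  immigration_rate: 0.06
  emigration_rate: 0.06
  alpha_turnover_rate: 0.1
  effects:
    beta0: -2.4
    beta_rank_avg: 0.5
    beta_both_infant: 1.0
    beta_one_infant: 0.0
    beta_immigrant: -1.0
# paths:
#   scans: data/scans.csv
#   agonistic: data/agonistic.csv
#   demography: data/demography.csv
lax: false
elo: {start: 1000, k: 100}
node_strength: weighted_degree   # or raw_rate
min_focals_per_window: 0
interval: 0.95
backend: mixedlm
models: [individual, dyadic, infant_gam, immigrant_gam]
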