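# Two-disease demonstration cohort: a coronary-artery-disease-like and a
# type-2-diabetes-like liability model. Run with
#   fampgs run --config examples/demo_config.yaml --out-dir out/demo --seed 1
n_families: 2000
seed: 1
generations: 3
birth_year_range: [1945, 1975]
n_children: 2
n_parent_siblings: 1
diseases:
  - disease_id: cad
    K: 0.12          # lifetime prevalence
    h2: 0.5          # liability heritability
    rho2: 0.3        # liability variance captured by the PRS
    c2: 0.05         # shared-family environment
    onset_mean: 62
    onset_sd: 11
  - disease_id: t2d
    K: 0.10
    h2: 0.4
    rho2: 0.2
    c2: 0.05
    onset_mean: 58
    onset_sd: 12
registry:
  death_registry_start: 1964
  discharge_registry_start: 1968
  cancer_registry_start: 1953
  death_registry_end: 2018
  followup_end: 2019
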