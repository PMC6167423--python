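# Two-compound synthetic demonstration study: spectra are generated with
# signatures placed at the packaged shift-table chemical shifts, two 4-group
# PLS-DA models are fitted (one per compound), per-dose fingerprints are
# extracted and mapped onto the curated core-metabolism demo network, and the
# highest-dose sub-networks of the two compounds are intersected/subtracted.
seed: 42
output_dir: fingernet_out

synth:
  compounds: [BPA, E2]
  signatures: shift_table      # plant effects at the packaged table shifts
  effect: 3.0                  # top-dose effect, in units of the noise SD
  n_bins: 200
  noise_sd: 1.0
  confounder_sd: 2.0

preprocess:
  normalize: true
  scaling: center_pareto
  screen_outliers: true
  exclude_outliers: false

chemometrics:
  folds: 7
  n_perm: 200
  n_osc: 1
  vip_threshold: 1.5
  alpha: 0.05
  max_components: 4
  tol_ppm: 0.02

network:
  # default: the packaged curated demo network; set `sbml: path/to/model.xml`
  # to use a genome-scale reconstruction instead
  weight_scheme: degree_squared
  side_compounds: default
  mapping: default

comparisons:
  - id: BPA_joint
    groups: [DMSO, BPA_1e-6M, BPA_1e-9M, BPA_1e-12M]
  - id: E2_joint
    groups: [DMSO, E2_1e-9M, E2_1e-12M, E2_1e-15M]

pairs:
  - [BPA_1e-6M_vs_control, E2_1e-9M_vs_control]
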