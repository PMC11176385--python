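# Example pipeline configuration for `regliab run-all`.
#
# Exactly one data source is used: either a `simulation` block (below) or
# `persons_path` + `diagnoses_path` pointing at register-shaped TSV files.

simulation:
  n_families: 50000          # nuclear families (2 founders + children each)
  children_per_family: 2
  birth_year_range: [1981, 2005]
  study_end: "2045-12-31"    # administrative censoring date
  disorder_c:                # the mental disorder of the pair
    label: SCZ
    K: 0.05                  # lifetime risk
    h2: 0.6                  # liability heritability
    onset_location: 23.0     # truncated-logistic onset, years
    onset_scale: 3.0
  disorder_f:                # the cardiometabolic disorder of the pair
    label: T2D
    K: 0.10
    h2: 0.4
    onset_location: 26.0
    onset_scale: 4.0
  rg: 0.3                    # genetic correlation between the two liabilities
  re: 0.15                   # environmental correlation
  death_hazard: 0.0002       # constant annual hazards
  emigration_hazard: 0.001

# To analyse register files instead, delete the simulation block and set:
# persons_path: registry/persons.tsv
# diagnoses_path: registry/diagnoses.tsv
# disorder_c: SCZ
# disorder_f: T2D
# birth_year_range: [1981, 2005]
# study_end: "2012-12-31"
# catalog_path: my_catalog.yaml   # optional; packaged ICD-10 default otherwise

# Optional published hazard ratios for the decomposition stage
# (TSV columns: disorder_c, disorder_f, hr, hr_lo, hr_hi); without it the
# phenotypic correlation is estimated from the cohort's 2x2 affection table.
# hr_table: hazard_ratios.tsv

a_R: 0.5          # additive relationship (full siblings / parent-offspring)
alpha: 0.05
m_tests: 1        # Bonferroni divisor for the rg significance call
seed: 7
output_dir: report
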