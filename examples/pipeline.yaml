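# Default self-generated run: simulate a cohort, QC, pseudobulk DE,
# derive NBIGS weights from the bulk cohort, score nuclei, correlate, mediate.
seed: 1
out_dir: placmed_out
# sim: {}            # SimConfig overrides, e.g. {n_samples: 10, n_genes: 1000}
# stages: [simulate, qc, pseudobulk, de, weights, score, correlate, mediate]
qc_params:
  min_genes: 200
  min_umi: 500
  max_mito_pct: 5.0
de_params:
  predictor: bmi_continuous
  covariates: [maternal_age, fetal_sex]
weights_params:
  outcomes: [sdq3]
  top_n: 500
  covariates: [maternal_age, maternal_education, delivery_mode, fetal_sex, batch]
score_params:
  method: ulm
  min_overlap: 5
mediate_params:
  cell_type: EVT
  side: maternal
  mediator_program: hypoxia
  outcome_program: nbigs_sdq3
  n_boot: 1000
  ci_level: 0.95
  unit: nucleus
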