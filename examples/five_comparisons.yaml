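# Five-comparison example over synthetic data, runnable as
#   kinsig run --config examples/five_comparisons.yaml
# One kinase (KIN_A) is activated in the RES and PERS conditions, so it is
# differential in three of the five comparisons - exactly the signature
# retention boundary.
seed: 3
output_dir: pipeline_out
generator:
  n_proteins: 400
  n_sites: 800
  n_kinases: 15
  n_replicates: 3
  conditions: [SENS, RES, PAR, GSI, PERS]
  reference_condition: SENS
  missing_rate: 0.03
  planted_kinases:
    - {name: KIN_A, delta: 1.2, n_substrates: 16, active_in: [RES, PERS]}
comparisons:
  - {name: RES_vs_SENS, test: sam, case: RES, control: SENS, fdr: 0.05, s0: 0.1}
  - {name: PERS_vs_PAR, test: sam, case: PERS, control: PAR, fdr: 0.05, s0: 0.1}
  - {name: PERS_vs_GSI, test: sam, case: PERS, control: GSI, fdr: 0.05, s0: 0.1}
  - {name: GSI_vs_SENS, test: one_sample, case: GSI, control: SENS, fdr: 0.05, s0: 0.1}
  - {name: PAR_vs_SENS, test: one_sample, case: PAR, control: SENS, fdr: 0.05, s0: 0.1}
min_per_group: 2
volcano:
  fdr: 0.01
  functional_min: 0.5
ksea:
  networkin_min: 3.0
  min_substrates: 4
  q_cut: 0.05
  min_significant: 3
  k: 3
enrichment:
  top_n: 100
connectivity:
  top_n: 150
synergy:
  epsilon: 0.1
  noise_sd: 0.02
  doses_a: [0.01, 0.03, 0.1, 0.3, 1.0, 3.0]
  doses_b: [0.01, 0.03, 0.1, 0.3, 1.0, 3.0]
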