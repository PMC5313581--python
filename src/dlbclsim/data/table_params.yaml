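# Published headline parameterisation: decision-node probabilities with their
# Beta/Dirichlet uncertainty hyperparameters, unit costs (GBP 2013), and the
# model constants. Point estimates are the empirical proportions; the
# hyperparameters are used only for probabilistic sensitivity draws.

model:
  discount_rate_annual: 0.035
  cure_threshold_years: 5
  max_age_years: 100
  annual_incident_cases_uk: 4880
  psa_iterations: 500
  prevalence_burn_in_years: 10
  age_distribution:
    beta: [3.73, 2.32]
    range_years: [18, 100]

decision_nodes:
  sex:
    outcomes: [male, female]
    bands:
      - {ages: [18, 40], p: [0.56, 0.44], alphas: [9, 7]}
      - {ages: [40, 50], p: [0.68, 0.32], alphas: [15, 7]}
      - {ages: [50, 60], p: [0.71, 0.29], alphas: [29, 12]}
      - {ages: [60, 70], p: [0.50, 0.50], alphas: [31, 31]}
      - {ages: [70, 80], p: [0.55, 0.45], alphas: [42, 35]}
      - {ages: [80, 101], p: [0.51, 0.49], alphas: [27, 26]}
  diagnostic_category:
    outcomes: [stage_ia, cns_involvement, standard, died_before_diagnosis]
    bands:
      - {ages: [18, 40], p: [0.06, 0.00, 0.94, 0.00], alphas: [2, 1, 16, 2]}
      - {ages: [40, 50], p: [0.09, 0.09, 0.77, 0.05], alphas: [3, 3, 18, 2]}
      - {ages: [50, 60], p: [0.15, 0.08, 0.75, 0.02], alphas: [7, 4, 32, 2]}
      - {ages: [60, 70], p: [0.06, 0.02, 0.90, 0.02], alphas: [5, 2, 57, 2]}
      - {ages: [70, 80], p: [0.12, 0.01, 0.75, 0.12], alphas: [10, 2, 59, 10]}
      - {ages: [80, 101], p: [0.05, 0.00, 0.89, 0.06], alphas: [4, 1, 48, 4]}
  initial_treatment:
    outcomes: [treated, not_treated]
    bands:
      - {ages: [18, 40], p: [0.94, 0.06], alphas: [15, 1]}
      - {ages: [40, 50], p: [0.95, 0.05], alphas: [21, 1]}
      - {ages: [50, 60], p: [0.96, 0.04], alphas: [39, 2]}
      - {ages: [60, 70], p: [0.88, 0.12], alphas: [55, 7]}
      - {ages: [70, 80], p: [0.75, 0.25], alphas: [58, 19]}
      - {ages: [80, 101], p: [0.54, 0.46], alphas: [29, 24]}
  refractory_line1:
    outcomes: [treated, not_treated]
    bands:
      - {ages: [18, 60], p: [0.86, 0.14], alphas: [6, 1]}
      - {ages: [60, 80], p: [0.33, 0.67], alphas: [4, 8]}
      - {ages: [80, 101], p: [0.00, 1.00], alphas: [0, 6]}
  relapse_line1:
    outcomes: [treated, not_treated]
    bands:
      - {ages: [18, 60], p: [0.93, 0.07], alphas: [14, 1]}
      - {ages: [60, 80], p: [0.53, 0.47], alphas: [8, 7]}
      - {ages: [80, 101], p: [1.00, 0.00], alphas: [2, 0]}
  refractory_line2:
    outcomes: [treated, not_treated]
    bands:
      - {ages: [18, 60], p: [0.50, 0.50], alphas: [4, 4]}
      - {ages: [60, 80], p: [0.50, 0.50], alphas: [3, 3]}
      - {ages: [80, 101], p: [0.00, 1.00], alphas: [0, 1]}
  relapse_line2:
    outcomes: [treated, not_treated]
    bands:
      - {ages: [18, 60], p: [0.50, 0.50], alphas: [1, 1]}
      - {ages: [60, 80], p: [0.00, 1.00], alphas: [0, 1]}
      - {ages: [80, 101], p: [0.00, 1.00], alphas: [0, 1]}
  refractory_line3:
    outcomes: [treated, not_treated]
    bands:
      - {ages: [18, 60], p: [0.50, 0.50], alphas: [0, 3]}
      - {ages: [60, 80], p: [0.00, 1.00], alphas: [0, 1]}
      - {ages: [80, 101], p: [0.00, 1.00], alphas: [0, 1], provenance: assumed_same_as_line2}
  relapse_line3:
    outcomes: [treated, not_treated]
    bands:
      - {ages: [18, 60], p: [0.50, 0.50], alphas: [1, 1], provenance: assumed_same_as_line2}
      - {ages: [60, 80], p: [0.00, 1.00], alphas: [0, 1], provenance: assumed_same_as_line2}
      - {ages: [80, 101], p: [0.00, 1.00], alphas: [0, 1], provenance: assumed_same_as_line2}

unit_costs:  # GBP 2013
  inpatient_spell: 797
  excess_bed_day: 243
  outpatient_first_single: 247
  outpatient_first_multi: 248
  outpatient_followup_single: 113
  outpatient_followup_multi: 174
  diagnostic_biopsy: 260
  staging_biopsy: 503
  ct_scan: 105
  mri_scan: 206
  pet_scan: 748
  ultrasound: 51
  ecg: 172
  echo: 322
  radiotherapy_planning: 769
  radiotherapy_fraction: 123
  chop_cycle: 289
  rchop_cycle: 1730
  rcvp_cycle: 1486
  codoxm_ivac_r_cycle: 6241
  idaram_cycle: 2006
  rdhap_cycle: 1952
  reshap_cycle: 3344
  minibeam_cycle: 446
  methotrexate_low_dose: 5
  methotrexate_high_dose: 861
  asct: 42000
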