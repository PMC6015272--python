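# Published summary statistics of the trial economic evaluation
# (two-arm RCT of a web-based type 2 diabetes self-management programme vs an
# information-only comparator, England, 2014 prices). These are the inputs for
# paper-replication mode and the calibration targets of the synthetic generator.
trial:
  n_intervention: 185
  n_control: 189
  n_centers: 21
  block_sizes: [2, 4, 6]

baseline:
  age_mean: {intervention: 64.9, control: 64.7}
  age_sd: {intervention: 9.5, control: 9.1}
  male_prop: {intervention: 0.69, control: 0.69}
  duration_mean: {intervention: 7.8, control: 8.2}
  duration_sd: {intervention: 5.7, control: 6.1}

intervention_cost:
  training_total: 3863          # nurse training 3785 + printed materials 78
  facilitation_nurse_hourly: 44 # practice-nurse hourly consultation rate
  facilitation_minutes: 20      # registration + introductory session
  booklet_unit_cost: 0.95
  capacity: 10000               # server capacity, active users
  per_participant_printed: 263  # 226 + 21 + 16, component-rounded

costs:  # health-service use, mean (SE), pounds
  baseline_12m: {intervention: [1792, 126], control: [2084, 164]}
  trial_12m: {intervention: [1816, 125], control: [2067, 144]}
  total_trial: {intervention: [2079, 125], control: [2067, 144]}

paid:   # mean (SE), 0-100 scale
  m0: {intervention: [18.1, 1.3], control: [19.9, 1.4]}
  m3: {intervention: [15.7, 1.2], control: [17.3, 1.3]}
  m12: {intervention: [14.5, 1.2], control: [17.6, 1.4]}

utility:  # EQ-5D-3L UK tariff, mean (SE)
  m0: {intervention: [0.793, 0.018], control: [0.766, 0.021]}
  m3: {intervention: [0.811, 0.016], control: [0.786, 0.024]}
  m12: {intervention: [0.793, 0.023], control: [0.736, 0.037]}

qaly:  # area under the utility curve over 12 months, mean (SE)
  intervention: [0.802, 0.016]
  control: [0.764, 0.023]

adjusted:  # mixed-model estimates adjusted for baseline outcome + covariates
  delta_cost: {point: 111, ci: [-156, 362]}
  delta_paid: {point: -1.9, ci: [-4.2, 0.4]}
  delta_qaly: {point: 0.020, ci: [-0.001, 0.044]}

completion:  # self-report questionnaire completion rates
  m3: {intervention: 0.77, control: 0.80}
  m12: {intervention: 0.70, control: 0.71}

complete_case:
  retained: {intervention: 96, control: 101}
  delta_cost: {point: 185, ci: [-145, 504]}
  delta_paid: {point: -1.6, ci: [-5.1, 1.4]}
  delta_qaly: {point: 0.010, ci: [-0.018, 0.044]}
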