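# Base-case input estimates, stage I ESCC (probabilities per 6-month cycle,
# costs US$ 2021, utilities in [0,1]).  Structural probabilities for the
# recurrence/metastasis states (p_lr_to_met 0.25, p_lr_to_dead 0.20,
# p_met_to_dead 0.50, p_comp_to_dead 0) are package defaults, not published
# estimates; override per strategy to change them.
stage_group: I
settings:
  horizon_years: 15.0
  cycle_length_years: 0.5
  annual_discount_rate: 0.03
  start_age_years: 60.0
  wtp_low: 5627.0
  wtp_high: 16881.0
  half_cycle_correction: false
strategies:
  EMR:
    p_complication_init: 0.069
    p_death_init: 0.0
    p_nr_to_lr: 0.0188
    p_nr_to_met: 0.0233
    p_nr_to_dead: 0.07
    cost_treatment: 1788.0
    u_nr: 0.693
    u_comp: 0.693
    u_lr: 0.693
    u_met: 0.75
  esophagectomy:
    p_complication_init: 0.119
    p_death_init: 0.055
    p_nr_to_lr: 0.0239
    p_nr_to_met: 0.0139
    p_nr_to_dead: 0.07
    cost_treatment: 3464.0
    u_nr: 0.693
    u_comp: 0.693
    u_lr: 0.693
    u_met: 0.75
  EMR_ablation:
    p_complication_init: 0.12
    p_death_init: 0.0
    p_nr_to_lr: 0.0287
    p_nr_to_met: 0.0151
    p_nr_to_dead: 0.082
    cost_treatment: 2136.0
    u_nr: 0.693
    u_comp: 0.693
    u_lr: 0.693
    u_met: 0.75
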