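# Base-case input estimates, stage II-III ESCC (probabilities per 6-month
# cycle, costs US$ 2021, utilities in [0,1]).  Structural probabilities for
# the recurrence/metastasis states are package defaults; see stage1_base.yaml.
stage_group: II_III
settings:
  horizon_years: 15.0
  cycle_length_years: 0.5
  annual_discount_rate: 0.03
  start_age_years: 60.0
  wtp_low: 5627.0
  wtp_high: 16881.0
  half_cycle_correction: false
strategies:
  CRT:
    p_complication_init: 0.17
    p_death_init: 0.04
    p_nr_to_lr: 0.0528
    p_nr_to_met: 0.0139
    p_nr_to_dead: 0.13
    cost_treatment: 2410.0
    u_nr: 0.76
    u_comp: 0.76
    u_lr: 0.76
    u_met: 0.75
  CRT_surgery:
    p_complication_init: 0.2
    p_death_init: 0.06
    p_nr_to_lr: 0.0151
    p_nr_to_met: 0.0123
    p_nr_to_dead: 0.08
    cost_treatment: 4762.0
    u_nr: 0.76
    u_comp: 0.76
    u_lr: 0.76
    u_met: 0.75
  esophagectomy:
    p_complication_init: 0.25
    p_death_init: 0.06
    p_nr_to_lr: 0.1085
    p_nr_to_met: 0.0309
    p_nr_to_dead: 0.085
    cost_treatment: 3464.0
    u_nr: 0.76
    u_comp: 0.76
    u_lr: 0.76
    u_met: 0.75
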