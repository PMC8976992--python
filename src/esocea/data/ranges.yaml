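# Published low/high bounds for one-way sensitivity analysis.  Parameters
# without a printed range are held at base case (degenerate range).
# strategy "all" applies the range to every strategy in the stage group
# (stage-level utilities); u_primary fans out to u_nr, u_comp, u_lr.
ranges:
- {strategy: esophagectomy, stage_group: I, parameter: p_complication_init, low: 0.119, high: 0.35}
- {strategy: esophagectomy, stage_group: I, parameter: p_death_init, low: 0.018, high: 0.111}
- {strategy: esophagectomy, stage_group: I, parameter: p_nr_to_met, low: 0.002, high: 0.0139}
- {strategy: EMR, stage_group: I, parameter: p_complication_init, low: 0.03, high: 0.069}
- {strategy: EMR, stage_group: I, parameter: p_nr_to_lr, low: 0.0076, high: 0.0426}
- {strategy: EMR_ablation, stage_group: I, parameter: p_complication_init, low: 0.068, high: 0.222}
- {strategy: EMR_ablation, stage_group: I, parameter: p_nr_to_lr, low: 0.014, high: 0.033}
- {strategy: all, stage_group: I, parameter: u_primary, low: 0.66, high: 0.71}
- {strategy: all, stage_group: I, parameter: u_met, low: 0.73, high: 0.77}
- {strategy: esophagectomy, stage_group: II_III, parameter: p_complication_init, low: 0.25, high: 0.39}
- {strategy: esophagectomy, stage_group: II_III, parameter: p_death_init, low: 0.0339, high: 0.111}
- {strategy: esophagectomy, stage_group: II_III, parameter: p_nr_to_dead, low: 0.0, high: 0.0905}
- {strategy: CRT_surgery, stage_group: II_III, parameter: p_complication_init, low: 0.17, high: 0.289}
- {strategy: CRT_surgery, stage_group: II_III, parameter: p_death_init, low: 0.04, high: 0.105}
- {strategy: CRT_surgery, stage_group: II_III, parameter: p_nr_to_lr, low: 0.003, high: 0.0151}
- {strategy: CRT_surgery, stage_group: II_III, parameter: p_nr_to_met, low: 0.0073, high: 0.0123}
- {strategy: CRT, stage_group: II_III, parameter: p_complication_init, low: 0.148, high: 0.28}
- {strategy: CRT, stage_group: II_III, parameter: p_death_init, low: 0.024, high: 0.058}
- {strategy: CRT, stage_group: II_III, parameter: p_nr_to_lr, low: 0.028, high: 0.0528}
- {strategy: CRT, stage_group: II_III, parameter: p_nr_to_met, low: 0.0139, high: 0.0221,
   note: 'source prints 0.0221-0.0139 (reverse order); sorted ascending'}
- {strategy: all, stage_group: II_III, parameter: u_primary, low: 0.74, high: 0.78}
- {strategy: all, stage_group: II_III, parameter: u_met, low: 0.73, high: 0.77}
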