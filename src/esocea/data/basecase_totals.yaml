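# Base-case discounted total cost per patient (US$ 2021) for each strategy.
# Used to calibrate the uniform alive-state per-cycle downstream cost
# (diagnosis, follow-up, terminal care) that bridges one-time treatment
# costs to total lifetime costs; see esocea.cea.fit_downstream_costs.
totals:
  I:
    EMR: 4485.6
    esophagectomy: 5582.6
    EMR_ablation: 4753.9
  II_III:
    CRT: 4738.9
    CRT_surgery: 6707.0
    esophagectomy: 7622.8
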