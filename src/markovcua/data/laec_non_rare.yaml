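settings:
  cycle_length_months: 3.0
  horizon_cycles: 20
  annual_discount_rate: 0.03
  wtp_threshold: 7500000.0
  half_cycle_correction: false
  followup_cost_year1: 45615.0
  followup_cost_later: 28480.0
  admission_cost: 1325370.0
  followup_in_first_cycle: false
start_state: no_late_ae
strategies:
- id: PBT
  treatment_fee: 1600000.0
  fee_fixed: true
- id: 3DCRT
  treatment_fee: 727600.0
  fee_fixed: true
states:
- id: no_late_ae
  label: No late adverse events
  utility: 0.91
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: rp_g1
  label: RP Grade 1
  utility: 0.87
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: rp_g2
  label: RP Grade 2
  utility: 0.83
  extra_cycle_cost: 62160.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: rp_g3
  label: RP Grade 3
  utility: 0.54
  extra_cycle_cost: 0.0
  entry_cost: 571120.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: pe_g1
  label: PE Grade 1
  utility: 0.87
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: pe_g2
  label: PE Grade 2
  utility: 0.76
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: override
  is_absorbing: false
  is_terminal_care: false
  followup_override_year1: 47165.0
  followup_override_later: 30030.0
- id: pe_g3
  label: PE Grade 3
  utility: 0.58
  extra_cycle_cost: 0.0
  entry_cost: 302700.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: pce_g2
  label: PCE Grade 2
  utility: 0.87
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: pce_g3
  label: PCE Grade 3
  utility: 0.63
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: pce_g3_pe_g2
  label: PCE Grade 3 + PE Grade 2
  utility: 0.57
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: override
  is_absorbing: false
  is_terminal_care: false
  followup_override_year1: 47165.0
  followup_override_later: 30030.0
- id: rp_g1_pe_g1
  label: RP Grade 1 + PE Grade 1
  utility: 0.87
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: rp_g1_pce_g2
  label: RP Grade 1 + PCE Grade 2
  utility: 0.87
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: drainage
  label: Pericardial drainage
  utility: 0.63
  extra_cycle_cost: 0.0
  entry_cost: 448220.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: pericardiotomy
  label: Pericardiotomy
  utility: 0.63
  extra_cycle_cost: 0.0
  entry_cost: 595641.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: resolved_pce
  label: Resolved PCE
  utility: 0.87
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: standard
  is_absorbing: false
  is_terminal_care: false
- id: bsc
  label: Best supportive care
  utility: 0.32
  extra_cycle_cost: 0.0
  entry_cost: 632100.0
  followup: none
  is_absorbing: false
  is_terminal_care: true
- id: death
  label: Death
  utility: 0.0
  extra_cycle_cost: 0.0
  entry_cost: 0.0
  followup: none
  is_absorbing: true
  is_terminal_care: false
rules:
- strategy: shared
  from: '*'
  to: bsc
  probability: 0.0542
  window_start: 1
  perturbable: false
- strategy: shared
  from: bsc
  to: death
  probability: 1.0
  window_start: 1
  perturbable: false
- strategy: shared
  from: rp_g3
  to: rp_g2
  probability: 0.25
  window_start: 1
- strategy: shared
  from: rp_g2
  to: rp_g2
  probability: 0.25
  window_start: 1
- strategy: shared
  from: rp_g2
  to: rp_g1
  probability: remainder
  window_start: 1
- strategy: shared
  from: pe_g3
  to: pe_g2
  probability: remainder
  window_start: 1
- strategy: shared
  from: pce_g3
  to: drainage
  probability: 0.1
  window_start: 1
- strategy: shared
  from: pce_g3_pe_g2
  to: drainage
  probability: 0.1
  window_start: 1
- strategy: shared
  from: drainage
  to: pce_g2
  probability: 0.617
  window_start: 1
- strategy: shared
  from: drainage
  to: pericardiotomy
  probability: remainder
  window_start: 1
- strategy: shared
  from: pericardiotomy
  to: resolved_pce
  probability: remainder
  window_start: 1
- strategy: PBT
  from: no_late_ae
  to: rp_g1
  probability: 0.095
  window_start: 1
  window_end: 4
- strategy: 3DCRT
  from: no_late_ae
  to: rp_g1
  probability: 0.046
  window_start: 1
  window_end: 4
- strategy: PBT
  from: no_late_ae
  to: rp_g2
  probability: 0.005
  window_start: 1
  window_end: 4
- strategy: 3DCRT
  from: no_late_ae
  to: rp_g2
  probability: 0.053
  window_start: 1
  window_end: 4
- strategy: PBT
  from: no_late_ae
  to: rp_g3
  probability: 0.0025
  window_start: 1
  window_end: 4
- strategy: 3DCRT
  from: no_late_ae
  to: rp_g3
  probability: 0.026
  window_start: 1
  window_end: 4
- strategy: PBT
  from: no_late_ae
  to: rp_g1_pe_g1
  probability: 0.157
  window_start: 1
  window_end: 4
- strategy: 3DCRT
  from: no_late_ae
  to: rp_g1_pe_g1
  probability: 0.179
  window_start: 1
  window_end: 4
- strategy: PBT
  from: no_late_ae
  to: rp_g1_pce_g2
  probability: 0.076
  window_start: 1
  window_end: 4
- strategy: 3DCRT
  from: no_late_ae
  to: rp_g1_pce_g2
  probability: 0.081
  window_start: 1
  window_end: 4
- strategy: PBT
  from: no_late_ae
  to: pe_g1
  probability: 0.008
  window_start: 1
  window_end: 12
- strategy: 3DCRT
  from: no_late_ae
  to: pe_g1
  probability: 0.041
  window_start: 1
  window_end: 12
- strategy: PBT
  from: no_late_ae
  to: pe_g2
  probability: 0.017
  window_start: 1
  window_end: 12
- strategy: 3DCRT
  from: no_late_ae
  to: pe_g2
  probability: 0.015
  window_start: 1
  window_end: 12
- strategy: PBT
  from: no_late_ae
  to: pe_g3
  probability: 0.0
  window_start: 1
  window_end: 12
- strategy: 3DCRT
  from: no_late_ae
  to: pe_g3
  probability: 0.06
  window_start: 1
  window_end: 12
- strategy: PBT
  from: no_late_ae
  to: pce_g2
  probability: 0.0024
  window_start: 1
  window_end: 12
- strategy: 3DCRT
  from: no_late_ae
  to: pce_g2
  probability: 0.02
  window_start: 1
  window_end: 12
- strategy: PBT
  from: no_late_ae
  to: pce_g3
  probability: 0.001
  window_start: 1
  window_end: 12
- strategy: 3DCRT
  from: no_late_ae
  to: pce_g3
  probability: 0.075
  window_start: 1
  window_end: 12
- strategy: PBT
  from: no_late_ae
  to: pce_g3_pe_g2
  probability: 0.003
  window_start: 1
  window_end: 12
- strategy: 3DCRT
  from: no_late_ae
  to: pce_g3_pe_g2
  probability: 0.028
  window_start: 1
  window_end: 12
utility_orderings:
- - rp_g1
  - rp_g2
  - rp_g3
- - pe_g1
  - pe_g2
  - pe_g3
- - pce_g2
  - pce_g3
  - pce_g3_pe_g2
param_links:
- - prob.shared.pce_g3>drainage
  - prob.shared.pce_g3_pe_g2>drainage
- - cost.followup_override_year1.pe_g2
  - cost.followup_override_year1.pce_g3_pe_g2
- - cost.followup_override_later.pe_g2
  - cost.followup_override_later.pce_g3_pe_g2
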