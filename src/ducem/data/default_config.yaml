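# Base-case configuration: anaprazole vs ilaprazole for duodenal ulcer,
# Chinese healthcare-system perspective, 2-week cycles over 48 weeks.
#
# Unit costs and utilities are published model inputs; the follow-up fee and
# the fixed programme cost are calibrated against the published per-arm cost
# totals and headline ICUR (see docs/methods.md, "Cost pathway").

seed: 20240607

arms:
  anaprazole:
    price_per_tablet: 27.25      # ¥ per 20 mg tablet, one tablet daily
    tablets_per_day: 1
    n_effective: 179             # matched effective sample size
  ilaprazole:
    price_per_tablet: 13.06      # ¥ per 5 mg tablet, two tablets daily
    tablets_per_day: 2
    n_effective: 129             # trial enrolment

transitions:
  anaprazole: {p_ah: 0.9253, p_hs: 0.9661}
  ilaprazole: {p_ah: 0.8957, p_hs: 0.9344}
  p_sr: 1.0                      # scar is a transient confirmation state
  p_recur: 0.0013                # recovery -> active, per 2-week cycle

cycles:
  n_cycles: 24
  cycle_length_weeks: 2
  days_per_cycle: 14
  treatment_cycles: 2            # initial 4-week course
  retreat_on_recurrence: true    # keep billing drug to active-state occupancy

utilities:
  A: 0.7030
  H: 0.7790
  S: 0.8420
  R: 1.0                         # recovery utility (convention, see methods)

costs:
  exam_cost: 467.7675            # examination panel, ¥
  gastroscopy_cost: 606.5550     # gastroscopy, ¥
  followup_cost_per_cycle: 25.805917   # calibrated follow-up/registration fee
  fixed_program_cost: 2769.724868      # calibrated residual direct medical cost

wtp:
  gdp_per_capita: 85698.0        # China per-capita GDP, 2022, ¥
  threshold: 85698.0             # 1x GDP per QALY

uncertainty:
  n_draws: 1000
  seed: 20240607
  dsa_pct: 0.10
  sample_transitions: true       # Beta draws for p_ah/p_hs at trial-size SEs
  ceac_grid_points: 500

# Anchor-arm (rabeprazole) summaries for the indirect comparison.  The source
# trials' anchor-arm results were not published in usable form: these are
# SYNTHETIC placeholder values supporting qualitative checks only.
comparison:
  anchor1_n: 218
  anchor1_healing_rate: 0.853
  anchor1_adr_rate: 0.102
  anchor2_n: 130
  anchor2_healing_rate: 0.820
  anchor2_adr_rate: 0.055
  comparator_n: 129
  comparator_healing_rate: 0.837
  comparator_adr_rate: 0.0698

# Budget impact block.  The published analysis did not disclose its
# epidemiology, market-share or price inputs; everything below is an
# ILLUSTRATIVE SYNTHETIC fixture of plausible magnitude.
bia:
  base_year: 2023
  horizon: 3
  eligible_patients_per_year: [19600000, 19800000, 20000000]
  consultation_rate: 0.35
  reimbursement_rate: 0.70
  fund_budget_per_year: [2.46e+12, 2.58e+12, 2.71e+12]
  new_drug: anaprazole
  drugs:
    anaprazole:
      course_cost: 763.00
      shares: [0.056, 0.095, 0.155]
    ilaprazole:
      course_cost: 731.36
      shares: [0.300, 0.290, 0.280]
    other_ppis:
      course_cost: 520.00
      shares: [0.644, 0.615, 0.565]
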