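# Default model configuration: five-state Markov cohort model of early
# Alzheimer's disease comparing lecanemab + SoC and aducanumab + SoC against
# standard of care (SoC) alone.  US healthcare-system perspective, 1-year
# cycles, lifetime horizon.  Schema documented in docs/methods.md.
#
# The `conventions` block records the frozen modelling conventions selected
# by the convention sweep (analysis/04_convention_sweep.py); all base-case,
# one-way and probabilistic analyses run under these settings.

conventions:
  hr_method: multiplicative    # hazard ratio scales the annual probability: p' = min(1, p*hr)
  half_cycle: false            # rewards attach to start-of-cycle occupancy
  age_cap: 100
  stop_tolerance: 1.0e-6

discount_rate: 0.03            # annual, applied to costs, LYs and QALYs
wtp: 150000.0                  # US$ per QALY gained

# Annual transition probabilities between alive states, reference (SoC) arm.
# Self-transitions are the residual and are never listed; death is governed
# by the mortality block below.
transitions:
  MCI:      {MILD: 0.32, MODERATE: 0.04, SEVERE: 0.01}
  MILD:     {MCI: 0.03, MODERATE: 0.36, SEVERE: 0.05}
  MODERATE: {MCI: 0.00, MILD: 0.04, SEVERE: 0.40}
  SEVERE:   {MCI: 0.00, MILD: 0.00, MODERATE: 0.02}

# Age-banded annual all-cause mortality, multiplied per state by the stage
# mortality hazard ratios (capped at probability 1).
mortality:
  bands:
    - {min_age: 65, max_age: 74, p: 0.02}
    - {min_age: 75, max_age: 84, p: 0.05}
    - {min_age: 85, max_age: null, p: 0.16}
  stage_hr:    {MCI: 1.82, MILD: 2.92, MODERATE: 3.85, SEVERE: 9.52}
  stage_hr_se: {MCI: 0.16, MILD: 0.19, MODERATE: 0.27, SEVERE: 0.37}

utilities:    {MCI: 0.73, MILD: 0.69, MODERATE: 0.53, SEVERE: 0.38}
utilities_se: {MCI: 0.02, MILD: 0.01, MODERATE: 0.01, SEVERE: 0.01}

# Annual non-drug costs (US$/year).  Outpatient and inpatient apply to every
# alive state; administration (infusion fees) applies only to arms with a
# drug price schedule, in proportion to the treated fraction.
costs:
  administration: 3654.17
  outpatient: 3237.26
  outpatient_se: 251.30
  inpatient: 17935.84
  inpatient_se: 1145.99

strategies:
  soc:
    treatment_rule: none
    start_age: 71.00
    start_age_se: 0.26
    # All three arms are simulated from the same starting state mix (the
    # antibody-trial cohort, 61.5% MCI): the published incremental results
    # are additive across the three pairwise comparisons, which requires a
    # common starting cohort.  The trial placebo arm's own mix (66.2% MCI)
    # can be restored with --override start_mci_fraction.soc=0.662.
    start_mci_fraction: 0.615
    aria_rate: 0.06
    aria_annual_cost: 66.73
    drug_price_schedule: []
  lecanemab:
    treatment_rule: while_early_AD
    start_age: 71.40
    start_age_se: 0.27
    start_mci_fraction: 0.615
    hr_progression: {MCI->MILD: 0.69, MILD->MODERATE: 0.69}
    aria_rate: 0.15
    aria_annual_cost: 154.82
    drug_price_schedule:
      - {from_cycle: 0, annual_price: 26500.00}
  aducanumab:
    # The aducanumab trial population is assumed identical to the lecanemab
    # trial population: starting age, starting state mix and discount rate
    # are inherited from (and track) the lecanemab arm.
    population: lecanemab
    treatment_rule: while_early_AD
    hr_progression: {MCI->MILD: 0.83}
    # The printed annual administration cost assumes the biweekly infusion
    # schedule (26 infusions/year); aducanumab is infused monthly
    # (13 infusions/year), so it incurs half of that annual fee.
    admin_frequency_factor: 0.5
    # No ARIA occurrence rate or monitoring cost is reported for aducanumab;
    # both are set equal to the lecanemab values (ARIA monitoring is < 0.6%
    # of annual drug cost, so this choice is immaterial at table precision).
    aria_rate: 0.15
    aria_annual_cost: 154.82
    drug_price_schedule:
      - {from_cycle: 0, annual_price: 20500.00}
      - {from_cycle: 1, annual_price: 28200.00}

# One-way sensitivity ranges.  Printed source limits where they exist
# (generally +/-20% of the base value; discount rate 0-8%, starting ages
# 65-75); aducanumab entries, which have no printed limits, use +/-20%.
osa_ranges:
  start_age.lecanemab: [65.00, 75.00]
  start_age.soc: [65.00, 75.00]
  hr.lecanemab.MCI->MILD: [0.55, 0.83]
  hr.lecanemab.MILD->MODERATE: [0.55, 0.83]
  hr.aducanumab.MCI->MILD: [0.664, 0.996]
  tp.MCI->MILD: [0.26, 0.38]
  tp.MCI->MODERATE: [0.03, 0.05]
  tp.MCI->SEVERE: [0.01, 0.01]
  tp.MILD->MCI: [0.02, 0.04]
  tp.MILD->MODERATE: [0.29, 0.43]
  tp.MILD->SEVERE: [0.04, 0.06]
  tp.MODERATE->MILD: [0.03, 0.05]
  tp.MODERATE->SEVERE: [0.32, 0.48]
  tp.SEVERE->MODERATE: [0.02, 0.02]
  aria_rate.lecanemab: [0.12, 0.18]
  aria_rate.soc: [0.05, 0.07]
  cost.drug.lecanemab: [21200.00, 31800.00]
  cost.drug.aducanumab: [16400.00, 24600.00]
  cost.administration: [2923.34, 4385.01]
  cost.outpatient: [2589.81, 3884.72]
  cost.inpatient: [14348.67, 21523.01]
  cost.aria.lecanemab: [123.86, 185.78]
  cost.aria.aducanumab: [123.86, 185.78]
  cost.aria.soc: [53.39, 80.08]
  utility.MCI: [0.58, 0.88]
  utility.MILD: [0.55, 0.83]
  utility.MODERATE: [0.42, 0.64]
  utility.SEVERE: [0.30, 0.46]
  mortality.65-74: [0.02, 0.03]
  mortality.75-84: [0.04, 0.06]
  mortality.85+: [0.13, 0.19]
  mortality_hr.MCI: [1.46, 2.18]
  mortality_hr.MILD: [2.34, 3.50]
  mortality_hr.MODERATE: [3.08, 4.62]
  mortality_hr.SEVERE: [7.62, 11.42]
  discount.lecanemab: [0.00, 0.08]
  discount.soc: [0.00, 0.08]
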