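# Base case for the Italian APL budget-impact model.
#
# Sources: national statistics (population funnel), the pivotal phase 3
# ATO+ATRA vs ATRA+chemotherapy trial (transition probabilities, adverse
# event probabilities), Italian 2013 tariffs and 2014 AIFA reimbursement
# lists (unit costs). Pharmacy totals are allocated across phases so that
# a patient completing treatment accrues exactly the first-line pharmacy
# total; see docs/methods.md for how the phase split was reconstructed.
schema_version: 1

population:
  total_population: 60021955
  aml_incidence_per_100k: 3.2
  apl_fraction: 0.06
  low_int_risk_fraction: 0.71
  treated_fraction: 1.0

uptake:          # market share of new patients starting ATO+ATRA
  year1: 0.10
  year2: 0.20
  year3: 0.30

horizon_months: 36

regimens:
  ato_atra:
    label: "ATO+ATRA"
    phases:
      induction_months: 1
      consolidation_months: 7
      maintenance_months: 0
    transition_probabilities:
      stable_to_event: 0.00084
      stable_to_death: 0.00058
      event_to_death: 0.00058
    pharmacy:
      first_line_total: 46814
      induction_total: 11998
      consolidation_total: 34816   # DSA base for the consolidation-phase cost
      maintenance_monthly: 0
    medical:
      induction_per_cycle: 7585
      consolidation_per_cycle: 398
      maintenance_per_cycle: 0
      post_treatment_per_cycle: 94
    disease_event_cost: 430
    second_line_total: null        # derived from course components when null
    ae_probabilities:
      induction:
        neutropenia: 0.46
        thrombocytopenia: 0.59
        hepatic_toxicity: 0.025
        fever_unknown_origin: 0.011
      consolidation_1:
        neutropenia: 0.06
        thrombocytopenia: 0.06
        hepatic_toxicity: 0.025
        fever_unknown_origin: 0.011
      consolidation_2:
        neutropenia: 0.06
        thrombocytopenia: 0.06
        hepatic_toxicity: 0.025
        fever_unknown_origin: 0.011
      consolidation_3:
        neutropenia: 0.04
        thrombocytopenia: 0.03
        hepatic_toxicity: 0.025
        fever_unknown_origin: 0.011

  atra_chemo:
    label: "ATRA+chemotherapy"
    phases:
      induction_months: 1
      consolidation_months: 3
      maintenance_months: 24
    transition_probabilities:
      stable_to_event: 0.00202
      stable_to_death: 0.00444
      event_to_death: 0.00444
    pharmacy:
      first_line_total: 6832
      induction_total: 868         # induction+consolidation chunk spread uniformly
      consolidation_total: 2604
      maintenance_monthly: 140     # reconstructed from published yearly pharmacy splits
    medical:
      induction_per_cycle: 8098
      consolidation_per_cycle: 6128
      maintenance_per_cycle: 173
      post_treatment_per_cycle: 94
    disease_event_cost: 430
    second_line_total: null
    ae_probabilities:
      induction:
        neutropenia: 0.79
        thrombocytopenia: 0.88
        hepatic_toxicity: 0.004
        fever_unknown_origin: 0.098
      consolidation_1:
        neutropenia: 0.35
        thrombocytopenia: 0.18
        hepatic_toxicity: 0.004
        fever_unknown_origin: 0.098
      consolidation_2:
        neutropenia: 0.76
        thrombocytopenia: 0.65
        hepatic_toxicity: 0.004
        fever_unknown_origin: 0.098
      consolidation_3:
        neutropenia: 0.25
        thrombocytopenia: 0.15
        hepatic_toxicity: 0.004
        fever_unknown_origin: 0.098

ae_unit_costs:   # euro per adverse event, by treatment phase
  induction:
    neutropenia: 206
    thrombocytopenia: 331
    hepatic_toxicity: 222
    fever_unknown_origin: 202
  consolidation:
    neutropenia: 66
    thrombocytopenia: 62
    hepatic_toxicity: 61
    fever_unknown_origin: 62
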