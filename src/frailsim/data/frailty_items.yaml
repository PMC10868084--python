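# 52-item cumulative-deficit frailty dictionary, version 1.
# Grouped by deficit domain: 20 chronic diseases, 8 sensory/physical
# impairments, 1 cognitive composite, 4 subjective symptoms/health status,
# 2 lifestyle risk factors, 15 ADL/IADL limitations, 1 polypharmacy,
# 1 living alone. Falls are intentionally excluded as an item.
schema_version: 1
groups:
  chronic_diseases:
    - angina
    - arrhythmia
    - arthritis
    - asthma
    - cancer
    - cataract
    - depression
    - diabetes
    - diabetic_eye_disease
    - diabetic_kidney_disease
    - glaucoma
    - heart_attack
    - heart_disease_other
    - heart_murmur
    - hypertension
    - high_cholesterol
    - lung_disease
    - macular_degeneration
    - osteoporosis
    - stroke
  sensory_physical:
    - seeing_difficulties
    - hearing_difficulties
    - slow_walking_speed
    - balance_problems
    - weak_grip_strength
    - weak_leg_strength
    - urinary_incontinence
    - significant_weight_loss
  cognitive:
    - cognitive_composite
  subjective:
    - self_reported_exhaustion
    - poor_self_rated_health
    - self_rated_pain
    - long_standing_illness
  lifestyle:
    - low_physical_activity
    - obesity
  adl_iadl:
    - adl_dressing
    - adl_walking_across_room
    - adl_bathing
    - adl_eating
    - adl_transferring_bed
    - adl_using_toilet
    - iadl_preparing_meals
    - iadl_shopping_groceries
    - iadl_using_telephone
    - iadl_taking_medications
    - iadl_housework_gardening
    - iadl_managing_money
    - iadl_using_map
    - iadl_difficulty_walking_100yds
    - iadl_climbing_stairs
  healthcare_contact:
    - polypharmacy_5plus
  social:
    - living_alone
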