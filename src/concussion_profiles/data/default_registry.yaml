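# Default symptom-to-profile mapping for the six concussion clinical profiles.
#
# The subsets approximate the AMSSM clinical-profile descriptions on the 22-item
# SCAT5 vocabulary; cognitive, anxiety_mood and ocular are defined by exactly
# seven symptoms.  Profiles intentionally share symptoms.  Replace this file to
# use an alternative operationalization.
profiles:
  vestibular:
    - dizziness
    - balance_problems
    - nausea_or_vomiting
    - feeling_like_in_a_fog
    - blurred_vision
  cognitive:
    - difficulty_concentrating
    - difficulty_remembering
    - feeling_slowed_down
    - feeling_like_in_a_fog
    - confusion
    - dont_feel_right
    - fatigue_or_low_energy
  fatigue:
    - fatigue_or_low_energy
    - drowsiness
    - trouble_falling_asleep
    - feeling_slowed_down
    - dont_feel_right
  anxiety_mood:
    - more_emotional
    - irritability
    - sadness
    - nervous_or_anxious
    - trouble_falling_asleep
    - difficulty_concentrating
    - dont_feel_right
  headache_migraine:
    - headache
    - pressure_in_head
    - neck_pain
    - nausea_or_vomiting
    - sensitivity_to_light
    - sensitivity_to_noise
  ocular:
    - blurred_vision
    - sensitivity_to_light
    - headache
    - pressure_in_head
    - difficulty_concentrating
    - fatigue_or_low_energy
    - dizziness
endorsement_min_severity: 1
threshold_rule: half_floor
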