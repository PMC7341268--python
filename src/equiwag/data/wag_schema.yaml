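# WAG indicator-question schema for the brick-kiln EARS survey.
#
# Five welfare categories, four main questions each, plus two alternate
# questions used when their main question cannot be answered in the field.
# `levels` maps each admissible response string to a welfare level
# (good / medium / bad).  Multi-select questions may carry several responses
# per equid; responses under `exclusive` (the "no findings" options) must not
# co-occur with any other response to the same question.
multiselect_delimiter: ";"
questions:
  # ---- nutrition -----------------------------------------------------------
  - id: body_condition
    prompt: Body condition score
    category: nutrition
    role: main
    multiselect: false
    levels:
      Very thin/poor: bad
      Thin/moderate: medium
      Ideal: good
      Fat: medium
      Very fat: bad
  - id: diet
    prompt: Is the equid getting an appropriate diet?
    category: nutrition
    role: main
    multiselect: true
    levels:
      Pasture: good
      Vitamins/minerals: good
      Browse: good
      Straw/stover: good
      Chopped fibre/chaff: good
      Hay: good
      Haylage: good
      Straights: medium
      Creep feed: medium
      Legumes/pulses: medium
      Cereal grains: bad
      Mix/muesli: bad
      Silage: bad
  - id: water_access_working
    prompt: Access to clean water during working period
    category: nutrition
    role: main
    multiselect: false
    levels:
      Free access: good
      Limited access: medium
      No access: bad
  - id: fibre_availability
    # Main question routinely unanswerable on site; the survey substitutes
    # water_point_housed.  Vocabulary shipped for completeness.
    prompt: For how long is fibre available
    category: nutrition
    role: main
    multiselect: false
    levels:
      Constant access: good
      Intermittent access: medium
      No fibre provided: bad
  - id: water_point_housed
    prompt: Presence of a clean water point (housed)
    category: nutrition
    role: alternate
    alternate_for: fibre_availability
    multiselect: false
    levels:
      Free access: good
      Limited access: medium
      No access: bad
  # ---- health --------------------------------------------------------------
  - id: lameness
    prompt: Signs of lameness
    category: health
    role: main
    multiselect: false
    levels:
      No lameness: good
      Lame but still moving: medium
      Severely lame: bad
  - id: coat_condition
    prompt: Is the equid's coat healthy?
    category: health
    role: main
    multiselect: false
    levels:
      "Yes": good
      "No": bad
  - id: skin_alterations
    prompt: Skin alterations
    category: health
    role: main
    multiselect: true
    exclusive:
      - No signs present
    levels:
      No signs present: good
      Scars: medium
      Alopecia: medium
      Swellings: medium
      Open wounds: bad
      Sarcoids: bad
  - id: illness_signs
    prompt: Obvious signs of illness
    category: health
    role: main
    multiselect: true
    exclusive:
      - No signs present
    levels:
      No signs present: good
      Eye discharge: bad
      Nasal discharge: bad
      Signs of diarrhoea: bad
      Discharge (penis or vulva): bad
      Abdominal pain: bad
  # ---- behaviour -----------------------------------------------------------
  - id: harmful_practices
    prompt: Harmful practices
    category: behaviour
    role: main
    multiselect: true
    exclusive:
      - "No"
    levels:
      "No": good
      Limb tethering or hobbling: bad
      Amputations or mutilations: bad
      Firing and hot branding: bad
      Rope noseband: bad
  - id: general_attitude
    prompt: General attitude of the equid at a distance
    category: behaviour
    role: main
    multiselect: false
    levels:
      At ease: good
      Alert and active: good
      Agitated, aggressive: bad
      Apathetic, depressed, withdrawn: bad
  - id: fear_signs
    prompt: Signs of fear and distress
    category: behaviour
    role: main
    multiselect: true
    exclusive:
      - No signs of fear and distress present
    levels:
      No signs of fear and distress present: good
      Head shyness: bad
      Unpredictable or sudden movements: bad
      Showing the whites of the eyes: bad
      Sudden startle responses: bad
      Aggressive behaviour: bad
      Trembling: bad
  - id: handler_interaction
    prompt: Handlers interaction when holding the equid
    category: behaviour
    role: main
    multiselect: false
    levels:
      Relaxed and confident: good
      Cautious/fearful: medium
      Assertive/indifferent: medium
      Aggressive: bad
  # ---- working -------------------------------------------------------------
  - id: working_hours
    prompt: Number of working hours per day
    category: working
    role: main
    multiselect: false
    levels:
      Less than or equal to 3 h: good
      More than 3, less than or equal to 6 h: good
      More than 6, less than or equal to 9 h: medium
      More than 9 h: bad
  - id: working_days
    prompt: Number of days worked per week
    category: working
    role: main
    multiselect: false
    levels:
      5 days or less: good
      6 days: medium
      7 days: bad
  - id: rest_breaks
    prompt: Does the equid have a rest break during the working day
    category: working
    role: main
    multiselect: false
    levels:
      Yes, equipment removed: good
      Yes, equipment not removed: medium
      "No": bad
  - id: age_started_working
    # Main question routinely unanswerable on site; the survey substitutes
    # shade_access.  Vocabulary shipped for completeness.
    prompt: Age the equid started working
    category: working
    role: main
    multiselect: false
    levels:
      4 years or older: good
      2 to 4 years: medium
      Younger than 2 years: bad
  - id: shade_access
    prompt: Does the equid have access to shade during breaks
    category: working
    role: alternate
    alternate_for: age_started_working
    multiselect: false
    levels:
      Access to shade: good
      Limited access to shade: medium
      No access to shade: bad
  # ---- housing -------------------------------------------------------------
  - id: housing_regime
    prompt: Housing regime
    category: housing
    role: main
    multiselect: false
    levels:
      Stabled equid - access to field: good
      Kept outside - access to shelter: good
      Indoor housing: medium
      Kept outside - no access to shelter: bad
  - id: environment_clean
    prompt: Is the environment clean and free from hazards
    category: housing
    role: main
    multiselect: false
    levels:
      "Yes": good
      "No": bad
  - id: stable_dimensions
    prompt: Dimensions of the stable/shelter?
    category: housing
    role: main
    multiselect: false
    levels:
      Satisfactory: good
      Not-Satisfactory: bad
  - id: lying_area
    prompt: Is there a clean, dry comfortable lying area
    category: housing
    role: main
    multiselect: false
    levels:
      "Yes": good
      "No": bad
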