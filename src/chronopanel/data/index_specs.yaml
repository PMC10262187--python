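# Default composite-index definitions.
#
# These are documented stand-ins with the same shape as the survey's
# composite variables (the survey's exact item wording and coding tables
# are not public): five 1-5 stress/time-pressure items summed, and twelve
# diagnosis yes/no items plus one general health item counted. Override
# any of this by editing a copy and loading it with
# chronopanel.features.load_index_specs().
time_stress:
  kind: sum
  max_missing: 1
  items:
    - stress_item_1   # general feeling of stress, 1-5
    - stress_item_2   # time pressure, 1-5
    - stress_item_3   # needs more regular sleep, 1-5
    - stress_item_4   # needs more time for self/family, 1-5
    - stress_item_5   # needs more time for career development, 1-5
diseases:
  kind: count
  max_missing: 1
  items:
    - disease_item_1   # heart and circulatory problems
    - disease_item_2   # high blood pressure
    - disease_item_3   # breathing problems
    - disease_item_4   # allergies
    - disease_item_5   # back and cervical pain
    - disease_item_6   # muscle and joint pain (arms/hands)
    - disease_item_7   # muscle and joint pain (legs/feet)
    - disease_item_8   # stomach and digestion problems
    - disease_item_9   # skin problems
    - disease_item_10  # severe headaches
    - disease_item_11  # diabetes
    - disease_item_12  # cancer
    - disease_item_13  # any health problem (general)
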