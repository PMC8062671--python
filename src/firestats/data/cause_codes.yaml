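# Raw ignition-cause vocabulary and its grouping.
#
# The 15 anthropogenic codes partition into three human-caused groups
# (transportation, activity, construction); lightning is the single natural
# cause; miscellaneous and unknown stand outside the natural/human dichotomy.
# The grouping is data so that agencies with different raw vocabularies can
# swap this file without touching code.
version: 1
groups:
  natural:
    - lightning
  human_transportation:
    - railroad
    - vehicle
    - aircraft
  human_activity:
    - equipment_use
    - smoking
    - campfire
    - debris
    - arson
    - playing_with_fire
    - firefighter_training
    - non_firefighter_training
    - escaped_prescribed_fire
    - illegal_alien_campfire
  human_construction:
    - powerline
    - structure
  miscellaneous:
    - miscellaneous
  unknown:
    - unknown
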