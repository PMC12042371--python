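# Operational areas and their pairwise land/water classification.
#
# The ten areas merge biogeographic provinces into units relevant for
# Magnoliaceae: eight Neotropical areas plus the Nearctic and Asia.  The
# classification drives the baseline dispersal-multiplier matrix
# (adjacent land 0.5, across water 0.25, non-adjacent pairs 0.25); it is
# a shipped, editable default — the area-pair classification is not a
# measured quantity and can be overridden by editing this file or
# supplying another one.
areas:
  - Andes-North
  - Brazil-Atlantic
  - Brazil-Boreal
  - Brazil-South
  - Caribbean
  - Mesoamerica
  - Mexican-Transition-Zone
  - Pacific
  - Nearctic
  - Asia
relations:
  adjacent-land:
    - [Andes-North, Pacific]
    - [Andes-North, Brazil-Boreal]
    - [Brazil-Boreal, Brazil-Atlantic]
    - [Brazil-Boreal, Brazil-South]
    - [Brazil-Atlantic, Brazil-South]
    - [Mesoamerica, Mexican-Transition-Zone]
    - [Mesoamerica, Pacific]
    - [Mexican-Transition-Zone, Nearctic]
    - [Nearctic, Asia]
  across-water:
    - [Caribbean, Andes-North]
    - [Caribbean, Brazil-Atlantic]
    - [Caribbean, Brazil-Boreal]
    - [Caribbean, Brazil-South]
    - [Caribbean, Mesoamerica]
    - [Caribbean, Mexican-Transition-Zone]
    - [Caribbean, Pacific]
    - [Caribbean, Nearctic]
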