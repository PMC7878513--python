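# Ordered category rules for the taxonomic-conservation classifier.
# First match wins; anything unmatched falls to the "other" catch-all.
# Clause values may be dataset ids or clade names from clades.toml.
#
#   present_in_all         every member carries the orthogroup
#   present_in_any_of_each at least one member of each listed clade carries it
#   present_in_any         at least one listed member carries it
#   absent_from_all        no listed member carries it
#   ignore                 datasets exempt from the exclusivity closure
#   exclusive              absent from every dataset the present_* clauses
#                          do not reference (minus `ignore`)

[[rules]]
name = "apinae"
present_in_all = ["outgroup", "orchid_bees", "bumblebees", "honeybees", "stingless_bees"]

[[rules]]
name = "corbiculates"
present_in_any_of_each = ["orchid_bees", "bumblebees", "honeybees", "stingless_bees"]
absent_from_all = ["outgroup"]

[[rules]]
name = "social_corbiculates"
present_in_any_of_each = ["bumblebees", "honeybees", "stingless_bees"]
absent_from_all = ["outgroup", "orchid_bees"]

[[rules]]
name = "bumblebees"
present_in_all = ["B_impatiens"]
present_in_any = ["B_terrestris_genome", "B_terrestris_transcriptome"]
exclusive = true

[[rules]]
name = "stingless_bees_f"
present_in_all = ["F_varia", "M_quadrifasciata", "T_angustula_transcriptome"]
exclusive = true

[[rules]]
name = "stingless_bees"
present_in_all = ["M_quadrifasciata", "T_angustula_transcriptome"]
ignore = ["F_varia"]
exclusive = true

[[rules]]
name = "bterrestris_g"
present_in_all = ["B_terrestris_transcriptome", "B_terrestris_genome"]
exclusive = true

[[rules]]
name = "species_specific_bterrestris"
present_in_all = ["B_terrestris_transcriptome"]
exclusive = true

[[rules]]
name = "species_specific_tangustula"
present_in_all = ["T_angustula_transcriptome"]
exclusive = true
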