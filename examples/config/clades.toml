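# Clade membership over the 11 datasets of the orthogroup comparison.
# Dataset ids are free strings; they must match the Orthogroups.tsv columns.

[clades]
outgroup = ["H_laboriosa"]
orchid_bees = ["E_dilemma", "E_mexicana"]
bumblebees = ["B_impatiens", "B_terrestris_genome", "B_terrestris_transcriptome"]
honeybees = ["A_cerana", "A_mellifera"]
stingless_bees = ["F_varia", "M_quadrifasciata", "T_angustula_transcriptome"]
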