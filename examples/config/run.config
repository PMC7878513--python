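# beecaste run configuration (key = value; '#' starts a comment)

seed = 0                # global seed; expanded into per-stage streams
resample_reps = 10000   # draws for every random-sampling test
min_coverage = 10       # bisulfite coverage filter (sites below are dropped)
alpha = 0.01            # significance threshold for all reports

# optional rule/clade overrides for the orthogroup classifier
# clade_config_path = examples/config/clades.toml
# category_rules_path = examples/config/rules.toml
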