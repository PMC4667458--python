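# Full-pipeline configuration for `lipidtrn run --config examples/config.yaml`.
# Paths are relative to where you invoke the command; generate the inputs first
# with `lipidtrn simulate --seed 1 --outdir sim`.
expression_tsv: sim/expression.tsv
modules_tsv: sim/modules.tsv
regulators_tsv: sim/regulators.tsv
outdir: out
# model_path: model.json          # optional: enables the knockdown screen
# id_map_tsv: id_map.tsv          # transcript_id -> model gene id

# filtering
fold_threshold: 1.0               # log2 units, strict inequality
min_period: 30.0                  # minutes, rule-2 run span
lipid_rule_mode: all              # 'all' or 'any' lipid-accumulation timepoints

# regulator influences
min_lag: 15.0                     # minutes
max_lag: 90.0
percentile: 5.0                   # distance threshold percentile
pool: best                        # 'best' pools per-pair best distances

# knockdown screen
kd_factor: 16.0                   # flux cap divisor (1/16 of wild-type flux)
viability_fraction: 0.10          # perturbed biomass must keep 10 % of wild type
gpr_mode: boolean                 # isozymes rescue a knockdown

seed: 1
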