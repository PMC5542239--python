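# Pipeline thresholds. Values are empirical defaults; every one can be
# overridden for sensitivity analyses.
vaf_germline_cut: 0.97
popdb_cut: 0.01
pon_cut: 0.03
pon_n: 480
loss_below: 1.0
gain_above: 4.0
fish_fold: 10.0
horizon_months: 36.0
seed: 0
min_callers: 1
strand_bias_p: 0.001
strand_bias_frac: 0.95
cluster_count: 3
cluster_window: 10
purity_grid_start: 0.05
purity_grid_stop: 1.0
purity_grid_step: 0.01
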