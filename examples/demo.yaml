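# Full pipeline from the printed resting-state coloring (no time series).
target_partition_path: examples/rs_partition.json
milp_mode: removal_only
alpha: 1.0
out_dir: fibsym_out
seed: 1
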