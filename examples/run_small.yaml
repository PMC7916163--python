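# Small end-to-end pipeline configuration for `ebcpanel run-all`.
# Simulates a scaled-down platform, analyses two contrasts and writes
# every artifact plus a reproducibility manifest to out_dir.
out_dir: scratch/cli_run
seed: 11
n_probesets: 400
n_human_mirnas: 200
probes_per_set: 4
n_healthy: 10
n_cancer: 10
planted_per_contrast: 3
planted_log2_shift: 1.5
contrasts: [cancer, histology]
n_trees: 50
filter_fraction: 0.1
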