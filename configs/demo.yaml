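# Demo-scale end-to-end run: simulate a 300-gene study and analyze it.
#   gcfate all --config configs/demo.yaml
out_dir: results/demo
seed: 7
n_genes: 300
min_length: 500
pb_threshold: 1.0
significance: 0.05
histogram_width: 0.007
tendency_bin: 500
n_bins: 20
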