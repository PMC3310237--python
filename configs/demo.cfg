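# Demo run: simulated 300 kb genome, all seven element architectures.
[simulate]
simulate = true
genome_length = 300000
genome_gc = 0.42
seed = 0

[discovery]
min_ir_len = 100
min_ir_identity = 80.0
min_tir_len = 50
max_span = 20000
tandem_window = 600
max_ext_truncation = 15
tsd_len_min = 9
tsd_len_max = 11
tsd_max_mismatch = 2

[phylogeny]
bootstrap_reps = 200
consensus_threshold = 0.40

[output]
out_dir = mulefinder_out
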