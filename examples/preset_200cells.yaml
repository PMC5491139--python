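# 200-cell preset: population means (arithmetic vs GFP-share-weighted)
# over a horizon long enough to watch partial synchronization develop.
n_cells: 200
t_end: 20000.0
dt_out: 10.0
seed: 0
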