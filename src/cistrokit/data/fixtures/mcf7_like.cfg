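# Synthetic luminal-A-like cistrome: two peak sets with a designed
# shared/specific overlap structure and class-dependent fragment piles.
fixture = mcf7_like
seed = 11910
n_era = 3000
n_nr2f2 = 1000
n_shared = 900
peak_width = 400
slot_spacing = 3000
genome_start = 10000
chrom = chrS
frag_mean_shared = 50.0
frag_mean_only_a = 10.0
frag_mean_only_b = 10.0
frag_length = 200
frag_jitter = 500
background_fragments = 2000
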