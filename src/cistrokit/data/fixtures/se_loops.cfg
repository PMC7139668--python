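# Super-enhancer mother/daughter regions with loop-linked peaks placed on
# an exact subset of regions, plus free-standing peaks per loop stratum.
fixture = se_loops
seed = 6321144
chrom = chrS
n_se = 1250
daughters_per_se = 2
mothers_looped = 790
daughters_looped = 286
mothers_peak_only = 60
extra_multi = 150
extra_single = 150
extra_none = 200
mother_width = 2000
daughter_width = 1000
peak_width = 400
anchor_pad = 100
se_spacing = 12000
frag_mean_multi = 60.0
frag_mean_single = 30.0
frag_mean_none = 8.0
frag_length = 200
frag_jitter = 500
background_fragments = 2000
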