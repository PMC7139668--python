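# 100-bp summit-window sequence classes with exact embedded GATA3 counts;
# non-embedded sequences are certified hit-free at the default threshold.
fixture = motif_freq
seed = 30911
motif = GATA3
seq_length = 100
gc = 0.5
class_shared_n = 10000
class_shared_embedded = 3091
class_only_era_n = 10000
class_only_era_embedded = 1764
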