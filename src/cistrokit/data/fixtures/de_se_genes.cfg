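# NB count matrix with designed up/down genes and SE-association flags.
fixture = de_se_genes
seed = 388524
n_genes = 2000
n_down = 388
n_up = 524
samples_per_group = 6
base_mean = 500.0
dispersion = 0.01
log2fc = 2.0
n_se_genes = 236
n_se_de = 99
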