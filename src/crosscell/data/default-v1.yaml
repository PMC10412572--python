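# Frozen "default-v1" synthetic study conditions.
# Two species, 5 shared cell types x 100 cells, 2000 one-to-one orthologs,
# 300 planted variable ortholog pairs at 2-fold, two anticorrelated 30-TF
# modules along pseudotime, 50 DE genes at 2-fold.
name: default-v1
n_types: 5
cells_per_type: 100
n_genes: 2000
n_planted_hvg: 300
effect_size: 2.0
nb_size: 2.0
libsize_sigma: 0.3
ortholog_noise: 0.1
n_decoy_one2many: 50
n_lowconf: 50
tf_module_sizes: [30, 30]
tf_trend_fold: 4.0
de_n_genes: 50
de_fold: 2.0
seed: 1
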