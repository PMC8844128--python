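# Demo pipeline configuration: a reduced-size end-to-end run.
seed = 7

[simulation]
n_sites = 20000
mean_depth = 29.0
error_rate = 0.01
n_blocks = 16

[populations]
presets = ["panama", "costa_rica", "mexico", "san_diego"]
n_references = 20
n_admixed = 15

[filters]
min_frac_covered = 0.63
min_depth = 3
snp_pval = 1e-6
thin = 100

[admixture]
k = [4]
n_restarts = 10
presence = 0.94
maf = 0.05

[pca]
n_pcs = 10

[diversity]
n_sites = 20000
n_blocks = 16
jackknife = true

[mito]
refs_per_clade = 3
seq_length = 15000
bootstrap = 2000
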