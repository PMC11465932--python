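# Default pipeline settings: the published analysis conditions.
# Attribute weights 45/35/20; Criterion-1 cut-off mean + 1*SD; network
# metrics cut-off mean + 1.5*SD; collective-influence radius 3; all
# shortest GN->BN paths used for the RbSP extension; scores and IVI
# rescaled to [1, 100].
weights: [0.45, 0.35, 0.20]
criterion1_k: 1.0
criterion2_k: 1.5
ci_radius: 3
path_policy: all_shortest
final_rescale_score: true
final_rescale_ivi: true
enrichment_mode: hypergeometric
genome_wide_p: 5.0e-8
hub_threshold: 300
seed: 0
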