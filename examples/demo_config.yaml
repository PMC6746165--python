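# Pipeline configuration for the bundled synthetic demo.
# Omitted design/effects fall back to the packaged study layout
# (113 pieces, 6 conditions, 3 V1 regions) and default planted effects.
outdir: plastphen_out
seed: 1
reference_condition: 5wk_normal
perplexity: 15.0
k: null            # null -> choose by the exponential-tau elbow rule
kmeans_restarts: 50
cluster_on: embedding   # or "features"
reduced_bootstrap: true # full-scale: false (10^6 population, 10^5 resamples)
bootstrap_convention: simulate_subcluster
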