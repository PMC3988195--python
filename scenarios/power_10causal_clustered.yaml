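# Full-design power scenario: 10 rare causal variants clustered within ~3 kb.
# Direction mixes studied: (10,0), (8,2), (5,5), (2,8), (0,10).
# Usage: rvcluster power --config scenarios/power_10causal_clustered.yaml \
#            --n-protective 0 --n-deleterious 10
pool_size: 10000
region_length: 20000
n_sites: 330
n_causal: 10
clustered: true
cluster_span: 3000
f0: 0.01
n_cases: 500
n_controls: 500
par_grid: "0.002,0.004,0.006,0.008,0.01"
replicates: 300
B: 200
alpha: 0.05
dmax: 20000
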