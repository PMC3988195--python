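# Full-design power scenario: 20 rare causal variants clustered within ~6 kb
# of a 20 kb region, 500 cases + 500 controls, PAR grid 0.2%..1%.
# Direction mixes studied: (n_protective, n_deleterious) in
# (20,0), (15,5), (10,10), (5,15), (0,20) -- set the two flags accordingly.
# Usage: rvcluster power --config scenarios/power_20causal_clustered.yaml \
#            --n-protective 0 --n-deleterious 20
pool_size: 10000
region_length: 20000
n_sites: 330
n_causal: 20
clustered: true
cluster_span: 6000
f0: 0.01
n_cases: 500
n_controls: 500
par_grid: "0.002,0.004,0.006,0.008,0.01"
replicates: 300
B: 200
alpha: 0.05
dmax: 20000
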