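# Full-design power scenario: causal variants approximately equally spaced
# across the whole 20 kb region (set --n-causal/--n-protective/--n-deleterious
# for the 20- or 10-variant designs).
# Usage: rvcluster power --config scenarios/power_nonclustered.yaml \
#            --n-causal 20 --n-deleterious 20
pool_size: 10000
region_length: 20000
n_sites: 330
clustered: false
f0: 0.01
n_cases: 500
n_controls: 500
par_grid: "0.002,0.004,0.006,0.008,0.01"
replicates: 300
B: 200
alpha: 0.05
dmax: 20000
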