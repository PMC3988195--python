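# Null calibration scenario (PAR = 0) at the full design; lower --replicates
# and -B for a desk-scale run (the packaged desk conditions are 2000
# replicates, 200+200 subjects, 70 sites, B=500).
# Usage: rvcluster type1 --config scenarios/type1_null.yaml
pool_size: 10000
region_length: 20000
n_sites: 330
n_causal: 20
clustered: true
cluster_span: 6000
n_deleterious: 20
par: 0.0
f0: 0.01
n_cases: 500
n_controls: 500
replicates: 2000
B: 500
alphas: "0.001,0.01,0.02,0.03,0.04,0.05"
dmax: 20000
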