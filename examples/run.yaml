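# Demo pipeline configuration: reduced MCMC so `smalltrend all` finishes in
# a few minutes on one CPU. Remove the mcmc section to use the reference
# protocol (3 chains x 10000 iterations, thin 5).
seed: 2021
out_dir: smalltrend_demo
mcmc:
  chains: 2
  burn_in: 300
  iterations: 2000
  thin: 4
joinpoint:
  k_max: 4
  n_perm: 199
  levels: [national, state, age, sex, sex_age]
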