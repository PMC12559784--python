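# Tiny end-to-end smoke configuration: same nine-state AML topology as
# aml_study.yaml but few subjects, few replicates and a coarse lambda grid.
chart:
  states: [active disease, CR1, early death, first relapse, death in CR1,
           CR2, death after relapse, second relapse, death in CR2]
  transitions: [[1, 2], [1, 3], [2, 4], [2, 5], [4, 6], [4, 7], [6, 8], [6, 9]]
  similar_pairs: [[3, 7], [4, 8]]
covariates:
  names: [X1, X2]
  laws: [[bernoulli, 0.5], [bernoulli, 0.5]]
dgp:
  baseline_hazards: [0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05]
  true_beta:
    - [1.5, 0.0, 1.2, -0.8, 0.0, 0.0, 1.2, -0.8]
    - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  N: 60
grid:
  lambdas: {min: 0.1, max: 100.0, num: 5}
  alphas: [1.0]
  gammas: [0.25, 1.0]
study:
  nsim: 2
  methods: [unpenalized, lasso, fsgl]
  fsgl_pairs: [[1.0, 0.25]]
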