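# Full-scale nine-state AML simulation study: 225 replicates of N = 1000
# subjects, constant baseline hazards 0.05, two Bernoulli(0.5) biomarkers,
# true effects 1.5 on transition 1, 1.2 on the fused pair (3, 7), -0.8 on
# the fused pair (4, 8).  The FSGL method scans the full 5 x 5 grid of
# (alpha, gamma) mixing weights; lambda is selected per pair by minimal
# GCV over 20 log-spaced values in [0.01, 500].  This is an overnight job;
# see smoke.yaml for a quick end-to-end check.
chart:
  states: [active disease, CR1, early death, first relapse, death in CR1,
           CR2, death after relapse, second relapse, death in CR2]
  transitions: [[1, 2], [1, 3], [2, 4], [2, 5], [4, 6], [4, 7], [6, 8], [6, 9]]
  similar_pairs: [[3, 7], [4, 8]]
covariates:
  names: [X1, X2]
  laws: [[bernoulli, 0.5], [bernoulli, 0.5]]
  continuous: []
  unpenalized: []
dgp:
  baseline_hazards: [0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05]
  true_beta:
    - [1.5, 0.0, 1.2, -0.8, 0.0, 0.0, 1.2, -0.8]
    - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  N: 1000
admm:
  rho0: 1.0
  tau: 2.0
  eta: 10.0
  eps_abs: 1.0e-4
  eps_rel: 1.0e-2
  max_iter: 500
  beta_update: hybrid
  tol_inner: 1.0e-6
  step_gd: 0.01
grid:
  lambdas: {min: 0.01, max: 500.0, num: 20}
  alphas: [0.0, 0.25, 0.5, 0.75, 1.0]
  gammas: [0.0, 0.25, 0.5, 0.75, 1.0]
study:
  nsim: 225
  methods: [unpenalized, lasso, fsgl]
  fsgl_pairs: [[0.0, 0.0], [0.0, 0.25], [0.0, 0.5], [0.0, 0.75], [0.0, 1.0],
               [0.25, 0.0], [0.25, 0.25], [0.25, 0.5], [0.25, 0.75], [0.25, 1.0],
               [0.5, 0.0], [0.5, 0.25], [0.5, 0.5], [0.5, 0.75], [0.5, 1.0],
               [0.75, 0.0], [0.75, 0.25], [0.75, 0.5], [0.75, 0.75], [0.75, 1.0],
               [1.0, 0.0], [1.0, 0.25], [1.0, 0.5], [1.0, 0.75], [1.0, 1.0]]
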