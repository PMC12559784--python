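# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `msfsgl`, in enough detail to audit or re-derive
any number the package produces.

## Model and likelihood

We model a continuous-time Markov multi-state process with finite state
space and transitions `q = 1..Q` through transition-specific proportional
hazards `h_q(t|x) = h_{0,q}(t) exp(beta_q' x)` with a common set of `P`
time-fixed covariates.  Data enter in long format: one row per subject per
transition at risk during a sojourn, with entry/exit times and event
indicator.  The partial likelihood is the product of per-transition Cox
partial likelihoods; stacking the `beta_q` covariate-major (all transition
copies of covariate 1, then covariate 2, ...) gives a `PQ`-dimensional
smooth problem whose Hessian is block diagonal across transitions.

Risk sets are left-truncated on half-open intervals: a row is at risk at
event time `t` of its stratum iff `tstart < t <= tstop`.  Ties use the
Breslow convention throughout, matching the Breslow estimator of the
cumulative baseline hazard that the package exports.  All risk-set sums
are computed by suffix sums over exit- and entry-sorted rows with a
max-subtraction (log-sum-exp) stabilization, so an evaluation of the
likelihood, score and Hessian costs `O(n log n)` in the number of rows.
Two independent routes to the score — the risk-set weighted-mean form and
the martingale-residual form `X'(delta - mu_hat)` with the Breslow plug-in
— are implemented and must agree; the exact partial-likelihood Hessian is
used by the solver, with the Poisson-type approximation `-X' diag(mu) X`
available only as a cross-check (it dominates the exact curvature by the
risk-set mean outer products and can differ substantially for strong
binary effects).

## Penalty

The FSGL penalty combines coefficient-wise L1 (sparsity), L1 on
differences of a covariate's effects across declared similar-transition
pairs (fusion), and per-transition group L2 norms (joint selection),
mixed by `alpha` (lasso vs. group) and `gamma` (sparse terms vs. fusion)
under an overall level `lam`.  Every term is a norm of a linear map of
`beta`; these maps are stacked into the penalty structure matrix `K` with
`M = PQ + s + PQ` rows when all covariates are penalized (`s` = one fusion
contrast per pair and covariate).

Choices:

- **Group weights** default to `w_q = sqrt(P_pen)`, the standard
  group-lasso group-size weighting; a `group_weight="size"` switch gives
  the literal `w_q = P_pen` variant.
- **Unpenalized covariates** (established clinical predictors) keep their
  lasso rows with penalty scaling factor `zeta = 0` — the auxiliary
  variable then carries them unshrunk — and are removed from the fusion
  and group blocks entirely, so nothing ever pulls them toward zero or
  toward each other.

## ADMM solver

The penalized problem is split as `min L(beta) + g(theta)` subject to
`K beta = theta` and solved with scaled-dual ADMM:

1. `beta`-step: minimize `L(beta) + rho/2 ||K beta - theta + u||^2` by
   warm-started damped Newton iterations (exact block-diagonal Hessian
   plus `rho K'K`), stopping when the augmented objective changes by less
   than `1e-6` relative; a single gradient step of size 0.01 precedes
   Newton on the first outer iteration (the hybrid scheme customary for
   Cox likelihoods).  Divergent steps fall back to step halving.
2. `theta`-step: exact blockwise soft-thresholding — scalar thresholds
   `lam*alpha*gamma*zeta/rho` on lasso rows, `lam*(1-gamma)/rho` on fusion
   rows, and joint vector thresholds `lam*(1-alpha)*gamma*w_q/rho` on the
   group blocks.
3. Dual ascent `u <- u + K beta - theta` and residual-balancing step-size
   adaptation (`tau = 2`, `eta = 10`, `rho_0 = 1`): `rho` grows when the
   primal residual exceeds 10x the dual residual and shrinks in the
   mirrored case; the scaled dual is rescaled by `rho_old/rho_new` so the
   unscaled multiplier is preserved across changes.

Stopping follows the usual primal/dual residual rule with
`eps_abs = 1e-4`, `eps_rel = 1e-2` and square-root dimension factors
(`sqrt(M)` for the primal residual in `R^M`, `sqrt(PQ)` for the dual in
`R^PQ`); a `strict_stopping` mode reproduces the linear-dimension variant
for comparison.  At `max_iter = 500` without convergence the solver warns
and returns the last iterate flagged accordingly.

The smooth iterate `beta` never hits exact zeros; the auxiliary variable
`theta` does.  Reported coefficients are therefore `theta` mapped back to
coordinate space, and "selected" means a nonzero lasso-block entry of
`theta`.  When `alpha*gamma = 0` there is no active lasso row: with
`gamma > 0` the group blocks provide the exact zeros, otherwise (pure
fusion) selection falls back to `|beta_hat| > 1e-8` — a documented
convention, since the fusion penalty alone does not produce sparsity.

## Tuning by GCV

For each preselected `(alpha, gamma)` the level `lam` minimizes
`GCV = L_bar / (n (1 - e/n)^2)` over a grid of 20 log-equally-spaced
values in `[0.01, 500]`, where `L_bar` is the *mean per-row* negative log
partial likelihood, `n` the number of long-format rows, and `e` the
effective number of parameters `tr[(H + Sigma)^{-1} H]` on the active set.
`Sigma` is the local quadratic approximation of the penalty assembled
blockwise from `K` (`sum_m lam_m w_m K_m' K_m / ||K_m beta_hat||` over
rows with `||K_m beta_hat|| > 1e-8`), which reduces to the classical
diagonal `lam/|beta_j|` form in the pure-lasso case; exact zeros are
excluded before the trace since the approximation is undefined there.

Two conventions deserve comment, both configurable:

- **Effective sample size.** Using the long-format row count `n` rather
  than the subject count in the `(1 - e/n)^2` correction is the package
  default: in pilot runs it is the convention whose selected levels are
  stable across replicates and whose GCV scale matches the per-row
  normalization of `L_bar`; the subject count is available via `gcv_n`.
  The constant numerator normalization itself never moves the argmin.
- **Tie-break.** Equal GCV values resolve toward the smallest `lam`
  (the sparser model).

Optional Brent refinement searches `lam` inside the bracketing grid
interval around the grid minimum and never returns a worse GCV.

## Simulator

Event histories are generated as nested competing-risks experiments: from
the current state, a single exponential sojourn at the total outgoing rate
followed by a categorical destination draw proportional to the
per-transition rates — identical in law to per-transition exponential
races.  Covariates for all subjects are drawn before any event times, so
covariate sets do not depend on realized path lengths.  The packaged AML
scenario uses the nine-state chart (eight transitions, similar pairs
(3, 7) and (4, 8)), constant baseline hazards 0.05, two independent
Bernoulli(0.5) biomarkers, N = 1000 subjects, and true effects 1.5
(transition 1), 1.2 (pair (3, 7)), -0.8 (pair (4, 8)), zero elsewhere —
five truly nonzero coefficients among sixteen.

No censoring mechanism is applied by default: the AML chart is acyclic, so
every path reaches an absorbing state.  An optional administrative horizon
exists for robustness experiments; charts with reachable cycles require
it.  Replicate `k` of a study uses a fresh generator seeded
`base_seed + k`, making every replicate independently reproducible.

What the simulator does *not* emulate: censoring by competing observation
processes, time-dependent covariates or effects, non-constant baseline
hazards, and covariate correlation.  Passing tests therefore demonstrate
correctness of the estimation machinery and selection behavior under a
clean Markov proportional-hazards world, not robustness to violations of
those assumptions.

## Study sizes and numerical tolerances

- The replicate-count rule `nsim = ceil(p(1-p)/mcse^2)` gives 225
  replicates for an anticipated TPR of 0.9 at target MCSE 0.02; the
  packaged full-study config uses that number.  The acceptance checks run
  a 50-replicate version — enough for the medians, modal selected levels
  and mean errors they assert, with MCSEs reported alongside.
- Selection metrics: TPR = TP/(TP+FN), FDR = FP/(TP+FP) with FDR = 0 when
  nothing is selected; medians over replicates use the lower-median
  convention; MSE over nonzero coefficients averages over the five true
  effects.
- Solver oracle comparisons use 1e-3 (unpenalized, against a stratified
  Cox reference) and 1e-2 (lasso corner, against a penalized Cox path
  solver at matched level) — the attainable agreement given the default
  ADMM stopping tolerances.  The fusion-equality check tightens
  `eps_abs`/`eps_rel` so the residual pair gap reflects the model rather
  than the stopping rule.
- Degenerate inputs: datasets with no events are rejected; zero-variance
  continuous covariates fail standardization explicitly; singular
  `H + Sigma` in the effective-parameter trace receives a `1e-8` ridge
  with a warning.

## Known limitations

- Same covariate set on every transition; no time-dependent covariates or
  effects; no frailties; Breslow ties only.
- The `beta`-step solves a `PQ`-dimensional Newton system; the
  implementation targets moderate dimensions (hundreds of coefficients),
  not `P >> N` genomics scale.
- GCV is the only tuning criterion; cross-validated partial likelihood,
  AIC/BIC and stability selection are out of scope.
- No post-selection inference: reported coefficients are shrunken
  estimates, and selection uncertainty is quantified only across
  simulation replicates.
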