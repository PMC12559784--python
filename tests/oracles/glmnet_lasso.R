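# Oracle generator for the stratified start-stop Cox lasso cross-check.
#
# Fits glmnet's Cox lasso on the stacked transition-specific design of the
# small simulated AML dataset (aml_dgp(N=200), generator seed 11, exported
# as long-format CSV).  glmnet minimizes the per-row-normalized negative
# partial log-likelihood plus lambda_g * ||beta||_1, so its lambda_g
# corresponds to lambda = lambda_g * n_rows in the unnormalized objective
# (confirmed by the KKT stationarity conditions at the returned solution).
# The coefficients printed by this script are frozen in
# tests/test_acceptance.py; the script is kept for provenance and is not
# executed by the test suite.
suppressMessages({library(survival); library(glmnet)})
d <- read.csv("oracle_data.csv")
Q <- 8
X <- matrix(0, nrow(d), 16)
for (p in 1:2) for (q in 1:Q) {
  rows <- d$trans == q
  X[rows, (p - 1) * Q + q] <- d[rows, paste0("X", p)]
}
y <- stratifySurv(Surv(d$Tstart, d$Tstop, d$status), d$trans)
for (lam in c(0.01, 0.02)) {
  f <- glmnet(X, y, family = "cox", standardize = FALSE, lambda = lam,
              thresh = 1e-14, maxit = 1e6)
  cat("lambda_g =", lam, "\n")
  cat(sprintf("%.8f ", as.numeric(coef(f))), "\n")
}
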