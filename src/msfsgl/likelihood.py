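"""Stacked multi-state Cox partial likelihood, derivatives and Breslow baseline.

The multi-state partial likelihood on long-format data factorizes over
transitions into stratified Cox partial likelihoods.  All quantities here
are computed stratum by stratum on the raw ``n x P`` covariates and then
placed into the stacked ``P*Q`` coordinate system, which is algebraically
identical to working with the stacked design matrix directly (the stacked
Hessian is block diagonal across transitions) but avoids multiplying
structural zeros.

Risk sets respect left truncation: row ``l`` is at risk at event time ``t``
of its stratum iff ``tstart_l < t <= tstop_l``.  Ties are handled by the
Breslow convention throughout, consistent with the Breslow estimator of the
cumulative baseline hazard.

Sign conventions: ``neg_log_partial_likelihood`` returns
``L(beta) = -log l(beta)`` (the quantity being *minimized*), while
:func:`score` and :func:`hessian` return the gradient and Hessian of
``log l(beta)``, so ``grad L = -score`` and ``hess L = -hessian`` (positive
semidefinite).
"""

from __future__ import annotations

import warnings

import numpy as np

from .state_space import StackedDesign


class _StratumData:
    """Precomputed, beta-independent risk-set structure for one transition."""

    __slots__ = (
        "rows", "Z", "delta", "n", "P", "event_times", "event_counts",
        "exit_sorted", "exit_order", "entry_sorted", "entry_order",
        "kx", "ke", "fail_rows", "z_fail_sum", "row_event_lo", "row_event_hi",
    )

    def __init__(self, rows: np.ndarray, Z: np.ndarray, delta: np.ndarray,
                 tstart: np.ndarray, tstop: np.ndarray) -> None:
        self.rows = rows
        self.Z = Z
        self.delta = delta
        self.n = len(rows)
        self.P = Z.shape[1]
        self.fail_rows = np.flatnonzero(delta == 1)
        fail_times = tstop[self.fail_rows]
        # distinct event times ascending, with tie multiplicities (Breslow)
        self.event_times, self.event_counts = np.unique(fail_times, return_counts=True)
        self.z_fail_sum = Z[self.fail_rows].sum(axis=0)
        # sort rows by exit and entry time for suffix-sum risk-set accumulation
        self.exit_order = np.argsort(tstop, kind="stable")
        self.exit_sorted = tstop[self.exit_order]
        self.entry_order = np.argsort(tstart, kind="stable")
        self.entry_sorted = tstart[self.entry_order]
        # at event time t: risk set {l: tstart_l < t <= tstop_l}
        #   S(t) = sum_{tstop >= t} w - sum_{tstart >= t} w
        self.kx = np.searchsorted(self.exit_sorted, self.event_times, side="left")
        self.ke = np.searchsorted(self.entry_sorted, self.event_times, side="left")
        # per-row range of event times inside (tstart_l, tstop_l], for
        # cumulative-hazard (Breslow plug-in) accumulation
        self.row_event_lo = np.searchsorted(self.event_times, tstart, side="right")
        self.row_event_hi = np.searchsorted(self.event_times, tstop, side="right")


class CoxWorkspace:
    """Per-design cache of stratum structures; reused across evaluations."""

    def __init__(self, design: StackedDesign) -> None:
        self.design = design
        self.Q = design.Q
        self.P = design.P
        self.strata: list[_StratumData] = []
        for q in range(1, self.Q + 1):
            rows = np.flatnonzero(design.trans == q)
            self.strata.append(
                _StratumData(
                    rows,
                    design.Z[rows],
                    design.delta[rows],
                    design.tstart[rows],
                    design.tstop[rows],
                )
            )

    def beta_matrix(self, beta: np.ndarray) -> np.ndarray:
        """Reshape a stacked covariate-major vector into a (P, Q) matrix."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.P * self.Q,):
            raise ValueError(f"beta must have length P*Q = {self.P * self.Q}")
        return beta.reshape(self.P, self.Q)


def _stratum_quantities(st: _StratumData, beta_q: np.ndarray, order: int):
    """Negative log-likelihood contribution, score and Hessian of one stratum.

    Returns (L_q, U_q, H_q, logS0, eta) where U_q/H_q are the gradient and
    Hessian of the stratum's log partial likelihood (None beyond `order`),
    and logS0 are the log risk-set score sums at the stratum's event times.
    """
    P = st.P
    if st.event_times.size == 0:
        zeros = np.zeros(P)
        return 0.0, zeros, np.zeros((P, P)), np.zeros(0), np.zeros(st.n)
    eta = st.Z @ beta_q
    c = eta.max() if st.n else 0.0
    w = np.exp(eta - c)

    # suffix sums over exit-sorted and entry-sorted rows
    wx = w[st.exit_order]
    we = w[st.entry_order]
    sx0 = np.concatenate([np.cumsum(wx[::-1])[::-1], [0.0]])
    se0 = np.concatenate([np.cumsum(we[::-1])[::-1], [0.0]])
    S0 = sx0[st.kx] - se0[st.ke]
    S0 = np.maximum(S0, 1e-300)
    logS0 = np.log(S0) + c
    L = float(st.event_counts @ logS0 - eta[st.fail_rows].sum())
    if order < 1:
        return L, None, None, logS0, eta

    wz = w[:, None] * st.Z
    sx1 = np.zeros((len(st.event_times), P))
    se1 = np.zeros_like(sx1)
    wzx = wz[st.exit_order]
    wze = wz[st.entry_order]
    cx1 = np.vstack([np.cumsum(wzx[::-1], axis=0)[::-1], np.zeros((1, P))])
    ce1 = np.vstack([np.cumsum(wze[::-1], axis=0)[::-1], np.zeros((1, P))])
    S1 = cx1[st.kx] - ce1[st.ke]
    zbar = S1 / S0[:, None]
    U = st.z_fail_sum - st.event_counts @ zbar
    if order < 2:
        return L, U, None, logS0, eta

    # second moments: suffix sums of w * z z^T flattened to P*P columns
    zz = (st.Z[:, :, None] * st.Z[:, None, :]).reshape(st.n, P * P)
    wzz = w[:, None] * zz
    cx2 = np.vstack([np.cumsum(wzz[st.exit_order][::-1], axis=0)[::-1], np.zeros((1, P * P))])
    ce2 = np.vstack([np.cumsum(wzz[st.entry_order][::-1], axis=0)[::-1], np.zeros((1, P * P))])
    S2 = (cx2[st.kx] - ce2[st.ke]).reshape(-1, P, P)
    zbar_outer = zbar[:, :, None] * zbar[:, None, :]
    V = S2 / S0[:, None, None] - zbar_outer
    H = -np.einsum("j,jkl->kl", st.event_counts.astype(float), V)
    return L, U, H, logS0, eta


def _evaluate(design: StackedDesign, beta: np.ndarray, order: int):
    ws = design.workspace()
    B = ws.beta_matrix(beta)
    P, Q = ws.P, ws.Q
    L = 0.0
    U = np.zeros(P * Q) if order >= 1 else None
    H = np.zeros((P * Q, P * Q)) if order >= 2 else None
    for q, st in enumerate(ws.strata, start=1):
        Lq, Uq, Hq, _, _ = _stratum_quantities(st, B[:, q - 1], order)
        L += Lq
        if order >= 1 and Uq is not None:
            cols = (np.arange(P)) * Q + (q - 1)
            U[cols] += Uq
            if order >= 2:
                H[np.ix_(cols, cols)] += Hq
    return L, U, H


def neg_log_partial_likelihood(design: StackedDesign, beta: np.ndarray) -> float:
    """Negative multi-state partial log-likelihood L(beta) = -log l(beta)."""
    return _evaluate(design, beta, order=0)[0]


def score(design: StackedDesign, beta: np.ndarray) -> np.ndarray:
    """Gradient of log l(beta) (the score vector), length P*Q."""
    return _evaluate(design, beta, order=1)[1]


def hessian(design: StackedDesign, beta: np.ndarray) -> np.ndarray:
    """Exact Hessian of log l(beta); symmetric, block diagonal, -H is PSD."""
    return _evaluate(design, beta, order=2)[2]


def breslow_baseline(design: StackedDesign, beta: np.ndarray) -> dict[int, dict[str, np.ndarray]]:
    """Breslow cumulative baseline hazard per transition.

    Returns ``{q: {"time", "increment", "cumulative"}}`` with jumps
    ``d_j / sum_{l in R_j} exp(eta_l)`` at the event times of transition q.
    Transitions without events get empty arrays (baseline identically 0).
    """
    ws = design.workspace()
    B = ws.beta_matrix(beta)
    out: dict[int, dict[str, np.ndarray]] = {}
    for q, st in enumerate(ws.strata, start=1):
        _, _, _, logS0, _ = _stratum_quantities(st, B[:, q - 1], order=0)
        inc = st.event_counts * np.exp(-logS0)
        out[q] = {
            "time": st.event_times.copy(),
            "increment": inc,
            "cumulative": np.cumsum(inc),
        }
    return out


def cumulative_hazard_residuals(design: StackedDesign, beta: np.ndarray) -> np.ndarray:
    """Estimated cumulative hazards mu_i per long-format row.

    ``mu_i = exp(eta_i) * [Lambda0_q(tstop_i) - Lambda0_q(tstart_i)]`` with
    the Breslow baseline plugged in; ``delta - mu`` are martingale residuals.
    """
    ws = design.workspace()
    B = ws.beta_matrix(beta)
    mu = np.zeros(design.n)
    for q, st in enumerate(ws.strata, start=1):
        _, _, _, logS0, eta = _stratum_quantities(st, B[:, q - 1], order=0)
        if st.event_times.size == 0:
            continue
        inc = st.event_counts * np.exp(-logS0)
        cum = np.concatenate([[0.0], np.cumsum(inc)])
        lam = cum[st.row_event_hi] - cum[st.row_event_lo]
        mu[st.rows] = np.exp(eta) * lam
    return mu


def score_residual_form(design: StackedDesign, beta: np.ndarray) -> np.ndarray:
    """Score computed as X^T (delta - mu) with the Breslow plug-in.

    Must agree with :func:`score`; kept as an independent route for
    cross-checking the martingale-residual identity.
    """
    mu = cumulative_hazard_residuals(design, beta)
    return design.X.T @ (design.delta - mu)


def poisson_hessian(design: StackedDesign, beta: np.ndarray) -> np.ndarray:
    """First-order Poisson approximation -X^T diag(mu) X of the Hessian.

    Coincides with the exact Hessian to first order; provided as an
    optional cross-check mode, not used by the solver.
    """
    mu = cumulative_hazard_residuals(design, beta)
    return -(design.X.T * mu) @ design.X


def newton_mle(
    design: StackedDesign,
    beta0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> tuple[np.ndarray, bool]:
    """Unpenalized stacked Cox MLE by damped Newton iterations.

    Minimizes L(beta) with step halving; a small ``ridge`` stabilizes
    near-separated strata.  Returns (beta_hat, converged).
    """
    PQ = design.P * design.Q
    beta = np.zeros(PQ) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    L, U, H = _evaluate(design, beta, order=2)
    for _ in range(max_iter):
        A = -H + ridge * np.eye(PQ)
        try:
            step = np.linalg.solve(A, U)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(A + 1e-8 * np.eye(PQ), U)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            Lc = neg_log_partial_likelihood(design, cand)
            if np.isfinite(Lc) and Lc <= L + 1e-12:
                break
            t /= 2
        else:
            warnings.warn("newton_mle: line search failed to improve", RuntimeWarning)
            return beta, False
        beta = cand
        drop = L - Lc
        L, U, H = _evaluate(design, beta, order=2)
        if drop < tol * (1.0 + abs(L)):
            return beta, True
    warnings.warn("newton_mle: maximum iterations reached", RuntimeWarning)
    return beta, False
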