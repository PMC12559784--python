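"""Fused sparse-group lasso penalty: structure matrix and penalty function.

The penalty on the stacked coefficient vector ``beta`` (length ``P*Q``) is

    p(beta) = lam * [ alpha*gamma * sum_pq zeta_pq |beta_pq|
                      + (1-gamma)  * sum_{(q,q') similar} sum_p |beta_pq - beta_pq'|
                      + (1-alpha)*gamma * sum_q w_q ||beta_q||_2 ]

with ``lam > 0`` the overall level, ``alpha`` trading global lasso against
transition-wise grouping and ``gamma`` trading both sparse terms against
the fusion term.  Every term is a norm of a linear map of ``beta``; the
stacked map is the penalty structure matrix ``K`` with three blocks —
unit rows (lasso), +1/-1 contrast rows (fusion) and per-transition
selector blocks (group) — which is exactly the splitting the ADMM solver
consumes.

Unpenalized covariates (e.g. established clinical predictors) keep their
lasso rows with penalty scaling factor ``zeta = 0`` (pass-through, so the
auxiliary variable still carries all coordinates) and are excluded from
the fusion and group blocks entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state_space import StateChart, column_index


@dataclass(frozen=True)
class FSGLParams:
    """Penalty hyperparameters: overall level and the two mixing weights."""

    lam: float
    alpha: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")


def reduction_mode(h: FSGLParams) -> str:
    """Which classical penalty the hyperparameter corner reduces to."""
    if h.gamma == 0.0:
        return "fusion"
    if h.alpha == 1.0 and h.gamma == 1.0:
        return "global-lasso"
    if h.alpha == 0.0 and h.gamma == 1.0:
        return "group"
    return "mixed"


@dataclass
class PenaltyStructure:
    """Penalty structure matrix K with block bookkeeping.

    Rows 0..PQ-1 are the lasso block (unit rows in covariate-major order,
    so lasso row m corresponds to stacked coordinate m), the next ``s``
    rows the fusion block, and the remaining rows the group blocks (one
    block of ``P_pen`` rows per transition, covering penalized covariates).
    """

    K: np.ndarray  # (M, PQ), entries in {-1, 0, 1}
    P: int
    Q: int
    zeta: np.ndarray  # (PQ,) per-coefficient penalty scaling, 0 = unpenalized
    fusion_rows: list[tuple[int, int, int]]  # (covariate p, q, q') per fusion row, 1-based
    group_blocks: list[tuple[int, slice, np.ndarray]]  # (q, row slice, column idx)
    group_weights: np.ndarray  # w_q per group block
    unpenalized: frozenset[int] = field(default_factory=frozenset)  # covariate ids, 1-based

    @property
    def M(self) -> int:
        return self.K.shape[0]

    @property
    def n_lasso(self) -> int:
        return self.P * self.Q

    @property
    def n_fusion(self) -> int:
        return len(self.fusion_rows)

    def row_levels(self, h: FSGLParams, rho: float) -> list[tuple[slice, float]]:
        """Soft-threshold levels kappa = lam_m * w_m / rho per row or block."""
        PQ = self.n_lasso
        s = self.n_fusion
        levels: list[tuple[slice, float]] = []
        lasso_levels = h.lam * h.alpha * h.gamma * self.zeta / rho
        levels.append((slice(0, PQ), lasso_levels))
        if s:
            levels.append((slice(PQ, PQ + s), h.lam * (1.0 - h.gamma) / rho))
        for (q, rows, _), w in zip(self.group_blocks, self.group_weights):
            levels.append((rows, h.lam * (1.0 - h.alpha) * h.gamma * w / rho))
        return levels

    def to_triplets(self):
        """Sparse (row, col, value, block) triplets for inspection/export."""
        import pandas as pd

        PQ, s = self.n_lasso, self.n_fusion
        rows, cols = np.nonzero(self.K)
        block = np.where(rows < PQ, "lasso", np.where(rows < PQ + s, "fusion", "group"))
        return pd.DataFrame(
            {"row": rows, "col": cols, "value": self.K[rows, cols].astype(int), "block": block}
        )


def build_penalty_structure(
    chart: StateChart,
    P: int,
    unpenalized: frozenset[int] | set[int] = frozenset(),
    group_weight: str = "sqrt",
) -> PenaltyStructure:
    """Assemble the lasso/fusion/group penalty structure for a state chart.

    Parameters
    ----------
    chart
        Multi-state chart providing Q transitions and the similar pairs.
    P
        Number of covariates shared across transitions.
    unpenalized
        1-based covariate indices exempt from penalization: their lasso
        rows get ``zeta = 0`` and they are dropped from fusion and group
        blocks.
    group_weight
        ``"sqrt"`` for w_q = sqrt(#penalized covariates) (standard
        group-lasso weighting) or ``"size"`` for w_q = #penalized
        covariates (literal group-size weighting).
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    unpenalized = frozenset(unpenalized)
    if not unpenalized <= set(range(1, P + 1)):
        raise ValueError("unpenalized must be a subset of 1..P")
    if group_weight not in ("sqrt", "size"):
        raise ValueError("group_weight must be 'sqrt' or 'size'")
    Q = chart.n_transitions
    PQ = P * Q
    penalized = [p for p in range(1, P + 1) if p not in unpenalized]
    P_pen = len(penalized)

    for q, q2 in chart.similar_pairs:
        if not (1 <= q <= Q) or not (1 <= q2 <= Q):
            raise ValueError(f"similar pair ({q}, {q2}) references unknown transition")

    fusion_rows = [(p, q, q2) for (q, q2) in chart.similar_pairs for p in penalized]
    s = len(fusion_rows)
    M = PQ + s + Q * P_pen
    K = np.zeros((M, PQ))

    # lasso block: identity on all PQ coordinates
    K[:PQ, :PQ] = np.eye(PQ)
    zeta = np.ones(PQ)
    for p in unpenalized:
        for q in range(1, Q + 1):
            zeta[column_index(p, q, Q)] = 0.0

    # fusion block: +1/-1 contrasts within a covariate across similar transitions
    for m, (p, q, q2) in enumerate(fusion_rows):
        K[PQ + m, column_index(p, q, Q)] = 1.0
        K[PQ + m, column_index(p, q2, Q)] = -1.0

    # group blocks: per transition, unit rows of the penalized covariates
    group_blocks: list[tuple[int, slice, np.ndarray]] = []
    r = PQ + s
    for q in range(1, Q + 1):
        cols = np.array([column_index(p, q, Q) for p in penalized], dtype=int)
        rows = slice(r, r + P_pen)
        for j, c in enumerate(cols):
            K[r + j, c] = 1.0
        group_blocks.append((q, rows, cols))
        r += P_pen

    w = np.sqrt(P_pen) if group_weight == "sqrt" else float(P_pen)
    return PenaltyStructure(
        K=K,
        P=P,
        Q=Q,
        zeta=zeta,
        fusion_rows=fusion_rows,
        group_blocks=group_blocks,
        group_weights=np.full(Q, w),
        unpenalized=unpenalized,
    )


def penalty_value(beta: np.ndarray, ps: PenaltyStructure, h: FSGLParams) -> float:
    """Evaluate the FSGL penalty at a stacked coefficient vector."""
    beta = np.asarray(beta, dtype=float)
    lasso = float(np.abs(beta) @ ps.zeta)
    fusion = 0.0
    Q = ps.Q
    for p, q, q2 in ps.fusion_rows:
        fusion += abs(beta[column_index(p, q, Q)] - beta[column_index(p, q2, Q)])
    group = 0.0
    for (q, rows, cols), w in zip(ps.group_blocks, ps.group_weights):
        group += w * float(np.linalg.norm(beta[cols]))
    return h.lam * (h.alpha * h.gamma * lasso + (1.0 - h.gamma) * fusion
                    + (1.0 - h.alpha) * h.gamma * group)
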