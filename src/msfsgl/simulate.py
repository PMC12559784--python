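"""Multi-state event-history simulation via nested competing-risks experiments.

Each subject starts in a given state with time-fixed covariates.  While the
current state ``l`` is non-absorbing, the sojourn time is drawn from an
exponential distribution with the total outgoing rate
``sum_q h0q * exp(beta_q' x)`` over the transitions leaving ``l``, and the
destination is drawn with probability proportional to the per-transition
rates — a single exponential race, mathematically identical to taking the
minimum of per-transition exponential latent times.  The walk repeats from
the destination state (continuous-time Markov chain) until an absorbing
state, or is administratively censored at an optional horizon.

The emitted table is in long format: one row per at-risk transition per
sojourn, with ``status = 1`` on the realized transition.

:func:`aml_dgp` packages the nine-state AML scenario used by the
simulation study: constant baseline hazards 0.05 on all eight transitions,
two independent Bernoulli(0.5) biomarkers, N = 1000 subjects, and true
effects 1.5 on transition 1, 1.2 on the fused pair (3, 7), -0.8 on the
fused pair (4, 8), and zero elsewhere (the second biomarker is pure noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_space import StateChart, aml_state_chart

#: Supported covariate laws: name -> sampler(rng, size, *args)
_COVARIATE_LAWS = {
    "bernoulli": lambda rng, size, p=0.5: rng.binomial(1, p, size).astype(float),
    "normal": lambda rng, size, mean=0.0, sd=1.0: rng.normal(mean, sd, size),
    "uniform": lambda rng, size, lo=0.0, hi=1.0: rng.uniform(lo, hi, size),
}


@dataclass(frozen=True)
class DGPConfig:
    """Data-generating process for a multi-state proportional hazards model.

    ``baseline_hazards[q-1]`` is the constant baseline rate of transition
    ``q``; ``true_beta`` is the P x Q matrix of log hazard ratios;
    ``covariate_laws`` lists one ``(name, *params)`` tuple per covariate.
    """

    chart: StateChart
    baseline_hazards: tuple[float, ...]
    true_beta: tuple[tuple[float, ...], ...]  # P rows of Q entries
    covariate_laws: tuple[tuple, ...] = (("bernoulli", 0.5), ("bernoulli", 0.5))
    N: int = 1000
    start_state: int = 1
    max_time: float | None = None
    covariate_names: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        Q = self.chart.n_transitions
        if len(self.baseline_hazards) != Q:
            raise ValueError(f"need one baseline hazard per transition (Q = {Q})")
        if any(h <= 0 for h in self.baseline_hazards):
            raise ValueError("baseline hazards must be positive")
        B = np.asarray(self.true_beta, dtype=float)
        if B.ndim != 2 or B.shape[1] != Q:
            raise ValueError("true_beta must be a P x Q matrix")
        if not np.isfinite(B).all():
            raise ValueError("true_beta must be finite")
        if len(self.covariate_laws) != B.shape[0]:
            raise ValueError("need one covariate law per covariate")
        if not self.covariate_names:
            object.__setattr__(
                self, "covariate_names",
                tuple(f"X{p}" for p in range(1, B.shape[0] + 1)),
            )

    @property
    def P(self) -> int:
        return len(self.covariate_laws)

    def beta_matrix(self) -> np.ndarray:
        return np.asarray(self.true_beta, dtype=float)

    def beta_stacked(self) -> np.ndarray:
        """True coefficients as a covariate-major stacked vector."""
        return self.beta_matrix().reshape(-1)

    def nonzero_mask(self) -> np.ndarray:
        return self.beta_stacked() != 0.0


def aml_true_beta() -> np.ndarray:
    """True P=2 x Q=8 coefficient matrix of the AML simulation scenario."""
    b1 = [1.5, 0.0, 1.2, -0.8, 0.0, 0.0, 1.2, -0.8]
    b2 = [0.0] * 8
    return np.array([b1, b2])


def aml_dgp(N: int = 1000, seed: int | None = None) -> DGPConfig:
    """The nine-state AML simulation scenario (see module docstring)."""
    return DGPConfig(
        chart=aml_state_chart(),
        baseline_hazards=(0.05,) * 8,
        true_beta=tuple(tuple(row) for row in aml_true_beta()),
        covariate_laws=(("bernoulli", 0.5), ("bernoulli", 0.5)),
        N=N,
        seed=seed,
    )


def draw_covariates(cfg: DGPConfig, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for law in cfg.covariate_laws:
        name, *params = law
        try:
            sampler = _COVARIATE_LAWS[name]
        except KeyError:
            raise ValueError(f"unknown covariate law {name!r}") from None
        cols.append(sampler(rng, cfg.N, *params))
    return np.column_stack(cols)


def simulate_paths(cfg: DGPConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate event histories and return them as a long-format table.

    Covariates are drawn for all subjects before any event times, so the
    covariate draw is invariant to realized path lengths under a fixed
    generator state.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chart = cfg.chart
    absorbing = chart.absorbing
    if cfg.start_state in absorbing:
        raise ValueError("start state must not be absorbing")
    if cfg.max_time is None:
        _check_absorbing_reachable(chart, cfg.start_state)
    B = cfg.beta_matrix()  # (P, Q)
    h0 = np.asarray(cfg.baseline_hazards, dtype=float)
    X = draw_covariates(cfg, rng)
    outgoing = {k: chart.outgoing(k) for k in range(1, chart.n_states + 1)}

    records: list[tuple] = []
    for i in range(cfg.N):
        x = X[i]
        state = cfg.start_state
        t = 0.0
        while state not in absorbing:
            qs = outgoing[state]
            rates = np.array([h0[q - 1] * np.exp(x @ B[:, q - 1]) for q in qs])
            total = rates.sum()
            sojourn = rng.exponential(1.0 / total)
            t_next = t + sojourn
            if cfg.max_time is not None and t_next > cfg.max_time:
                for q in qs:
                    records.append((i + 1, q, t, cfg.max_time, 0, *x))
                break
            dest_idx = rng.choice(len(qs), p=rates / total)
            for j, q in enumerate(qs):
                records.append((i + 1, q, t, t_next, int(j == dest_idx), *x))
            state = chart.target(qs[dest_idx])
            t = t_next
    columns = ["id", "trans", "Tstart", "Tstop", "status", *cfg.covariate_names]
    return pd.DataFrame.from_records(records, columns=columns)


def _check_absorbing_reachable(chart: StateChart, start: int) -> None:
    """Without a horizon, every state reachable from the start must lead
    to an absorbing state (otherwise paths could cycle forever)."""
    # simple cycle check on the reachable subgraph
    reachable = {start}
    frontier = [start]
    while frontier:
        k = frontier.pop()
        for q in chart.outgoing(k):
            to = chart.target(q)
            if to not in reachable:
                reachable.add(to)
                frontier.append(to)
    # DFS cycle detection
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {k: WHITE for k in reachable}

    def visit(k: int) -> None:
        color[k] = GRAY
        for q in chart.outgoing(k):
            to = chart.target(q)
            if color[to] == GRAY:
                raise ValueError(
                    "state chart has a reachable cycle; set max_time to bound paths"
                )
            if color[to] == WHITE:
                visit(to)
        color[k] = BLACK

    visit(start)


def race_probability(cfg: DGPConfig, state: int, x: np.ndarray) -> dict[int, float]:
    """Closed-form exit probabilities P(exit via q) = h_q(x) / sum h(x)."""
    B = cfg.beta_matrix()
    qs = cfg.chart.outgoing(state)
    rates = np.array([cfg.baseline_hazards[q - 1] * np.exp(x @ B[:, q - 1]) for q in qs])
    probs = rates / rates.sum()
    return dict(zip(qs, probs))
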