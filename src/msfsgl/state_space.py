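"""Multi-state model structure and the stacked transition-specific design.

A multi-state model is described by a :class:`StateChart`: a finite set of
states, directed transitions between them, and an optional set of "similar"
transition pairs whose covariate effects will be fused by the penalty.
Event-history data enter in *long format*: one row per subject per
transition for which the subject is at risk during a sojourn, with entry
time, exit time and an event indicator.  :func:`expand_design` turns a long
table into the stacked design matrix with one column per
(covariate, transition) combination, giving ``P * Q`` regression
coefficients for ``P`` covariates and ``Q`` transitions.

Column order is *covariate-major* throughout the package: the column of
covariate ``p`` (1-based) at transition ``q`` (1-based) is
``(p - 1) * Q + q``.  :func:`column_index` is the single authoritative
definition of this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Required leading columns of a long-format table; remaining columns are
#: interpreted as covariates.
LONG_FORMAT_COLUMNS = ("id", "trans", "Tstart", "Tstop", "status")


def column_index(p: int, q: int, Q: int) -> int:
    """Zero-based stacked column of covariate ``p`` at transition ``q`` (1-based).

    Covariate-major order: the stacked coefficient vector is
    ``(beta_{1,1}, ..., beta_{1,Q}, beta_{2,1}, ..., beta_{P,Q})``.
    """
    return (p - 1) * Q + (q - 1)


@dataclass(frozen=True)
class StateChart:
    """States, directed transitions and similar-transition pairs.

    Parameters
    ----------
    states
        Ordered state labels; state ids are 1-based positions in this list.
    transitions
        Ordered ``(from_state, to_state)`` pairs of 1-based state ids;
        transition ids are 1-based positions in this list.
    similar_pairs
        Unordered pairs ``(q, q')`` of transition ids whose covariate
        effects are treated as similar (candidates for fusion).
    """

    states: tuple[str, ...]
    transitions: tuple[tuple[int, int], ...]
    similar_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def absorbing(self) -> frozenset[int]:
        """State ids with no outgoing transition."""
        sources = {frm for frm, _ in self.transitions}
        return frozenset(k for k in range(1, self.n_states + 1) if k not in sources)

    def outgoing(self, state: int) -> list[int]:
        """Transition ids leaving ``state``."""
        return [q for q, (frm, _) in enumerate(self.transitions, start=1) if frm == state]

    def target(self, q: int) -> int:
        return self.transitions[q - 1][1]


def validate_state_chart(chart: StateChart) -> StateChart:
    """Check the chart invariants; return the chart unchanged if valid.

    Raises
    ------
    ValueError
        On the first violated invariant: a transition referencing an
        unknown or non-distinct state, a duplicated (from, to) pair, or a
        similar pair whose members are invalid or not distinct.
    """
    K = chart.n_states
    seen: set[tuple[int, int]] = set()
    for q, (frm, to) in enumerate(chart.transitions, start=1):
        if not (1 <= frm <= K) or not (1 <= to <= K):
            raise ValueError(f"transition {q} references unknown state: ({frm}, {to})")
        if frm == to:
            raise ValueError(f"transition {q} must join two distinct states")
        if (frm, to) in seen:
            raise ValueError(f"duplicate transition ({frm}, {to})")
        seen.add((frm, to))
    Q = chart.n_transitions
    for q, q2 in chart.similar_pairs:
        if q == q2:
            raise ValueError("similar pair must join distinct transitions")
        if not (1 <= q <= Q) or not (1 <= q2 <= Q):
            raise ValueError(f"similar pair ({q}, {q2}) references unknown transition")
    return chart


def aml_state_chart() -> StateChart:
    """The nine-state AML disease-pathway chart with eight transitions.

    States: 1 active disease, 2 first complete remission (CR1),
    3 early death, 4 first relapse, 5 death in CR1, 6 second complete
    remission (CR2), 7 death after relapse, 8 second relapse,
    9 death in CR2.  Similar transitions: (3, 7) — CR1 to first relapse
    and CR2 to second relapse — and (4, 8) — CR1 to death in CR1 and
    CR2 to death in CR2.
    """
    chart = StateChart(
        states=(
            "active disease",
            "CR1",
            "early death",
            "first relapse",
            "death in CR1",
            "CR2",
            "death after relapse",
            "second relapse",
            "death in CR2",
        ),
        transitions=(
            (1, 2),  # 1: active disease -> CR1
            (1, 3),  # 2: active disease -> early death
            (2, 4),  # 3: CR1 -> first relapse
            (2, 5),  # 4: CR1 -> death in CR1
            (4, 6),  # 5: first relapse -> CR2
            (4, 7),  # 6: first relapse -> death after relapse
            (6, 8),  # 7: CR2 -> second relapse
            (6, 9),  # 8: CR2 -> death in CR2
        ),
        similar_pairs=((3, 7), (4, 8)),
    )
    return validate_state_chart(chart)


def validate_long_format(data: pd.DataFrame, chart: StateChart | None = None) -> pd.DataFrame:
    """Validate a long-format table (one row per subject x at-risk transition).

    Checks the required columns, ``Tstart < Tstop`` on every row, binary
    status, and — when a chart is given — that every transition id exists.
    """
    missing = [c for c in LONG_FORMAT_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"long-format table is missing columns: {missing}")
    if len(data) == 0:
        raise ValueError("long-format table is empty")
    tstart = data["Tstart"].to_numpy(dtype=float)
    tstop = data["Tstop"].to_numpy(dtype=float)
    if np.any(tstart < 0):
        raise ValueError("Tstart must be nonnegative")
    if np.any(tstart >= tstop):
        bad = int(np.argmax(tstart >= tstop))
        raise ValueError(f"Tstart must be < Tstop (violated at row {bad})")
    status = data["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be 0/1")
    trans = data["trans"].to_numpy()
    if chart is not None:
        known = np.arange(1, chart.n_transitions + 1)
        if not np.isin(trans, known).all():
            unknown = sorted(set(trans) - set(known.tolist()))
            raise ValueError(f"unknown transition ids in data: {unknown}")
    return data


def covariate_columns(data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c not in LONG_FORMAT_COLUMNS]


@dataclass
class StackedDesign:
    """Stacked transition-specific design for the multi-state partial likelihood.

    ``X`` has one column per (covariate, transition) pair in covariate-major
    order; row ``i`` carries the subject's ``P`` covariate values in the
    columns of the row's transition and zeros elsewhere.  ``Z`` keeps the
    raw ``n x P`` covariates for per-stratum computations; the two encode
    the same information.
    """

    X: np.ndarray  # (n, P*Q) stacked design
    Z: np.ndarray  # (n, P) per-row covariates
    delta: np.ndarray  # (n,) event indicators
    trans: np.ndarray  # (n,) transition id per row, 1..Q
    tstart: np.ndarray  # (n,) entry times
    tstop: np.ndarray  # (n,) exit times
    subject: np.ndarray  # (n,) subject ids
    covariate_names: tuple[str, ...]
    Q: int
    scale_factors: np.ndarray = field(default=None)  # (P*Q,) standardization scales

    def __post_init__(self) -> None:
        if self.scale_factors is None:
            self.scale_factors = np.ones(self.X.shape[1])
        self._workspace = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return len(self.covariate_names)

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject))

    def coefficient_labels(self) -> list[str]:
        """Stacked coefficient labels ``name.q`` in covariate-major order."""
        return [f"{name}.{q}" for name in self.covariate_names for q in range(1, self.Q + 1)]

    def workspace(self):
        """Cached per-stratum risk-set structure (built on first use)."""
        if self._workspace is None:
            from .likelihood import CoxWorkspace

            self._workspace = CoxWorkspace(self)
        return self._workspace


def expand_design(
    data: pd.DataFrame,
    chart: StateChart,
    covariates: Sequence[str] | None = None,
) -> StackedDesign:
    """Expand a long-format table into the stacked design matrix.

    Each row keeps exactly ``P`` structurally nonzero entries, placed in
    the columns of the row's transition under covariate-major order.
    """
    validate_long_format(data, chart)
    if covariates is None:
        covariates = covariate_columns(data)
    if len(covariates) < 1:
        raise ValueError("at least one covariate column is required")
    Q = chart.n_transitions
    P = len(covariates)
    Z = data[list(covariates)].to_numpy(dtype=float)
    trans = data["trans"].to_numpy(dtype=int)
    n = len(data)
    X = np.zeros((n, P * Q))
    rows = np.arange(n)
    for p in range(1, P + 1):
        cols = (p - 1) * Q + (trans - 1)
        X[rows, cols] = Z[:, p - 1]
    return StackedDesign(
        X=X,
        Z=Z,
        delta=data["status"].to_numpy(dtype=float),
        trans=trans,
        tstart=data["Tstart"].to_numpy(dtype=float),
        tstop=data["Tstop"].to_numpy(dtype=float),
        subject=data["id"].to_numpy(),
        covariate_names=tuple(covariates),
        Q=Q,
    )


def standardize(design: StackedDesign, continuous: Iterable[str]) -> StackedDesign:
    """Scale continuous covariates by their empirical standard deviation.

    Each stacked column of a continuous covariate is divided by the SD of
    that covariate over the rows of the column's transition (no centering,
    which would break the structural zeros).  Binary/untouched columns keep
    scale factor 1.  Fitted coefficients on the standardized scale are
    mapped back with :func:`back_transform`.
    """
    continuous = set(continuous)
    unknown = continuous - set(design.covariate_names)
    if unknown:
        raise ValueError(f"unknown continuous covariates: {sorted(unknown)}")
    Q = design.Q
    scale = design.scale_factors.copy()
    X = design.X.copy()
    Z = design.Z.copy()
    for p, name in enumerate(design.covariate_names, start=1):
        if name not in continuous:
            continue
        for q in range(1, Q + 1):
            mask = design.trans == q
            col = column_index(p, q, Q)
            if not mask.any():
                continue
            sd = float(np.std(design.Z[mask, p - 1]))
            if sd <= 0:
                raise ValueError(f"zero-variance column for covariate {name!r}, transition {q}")
            X[mask, col] = design.X[mask, col] / sd
            Z[mask, p - 1] = design.Z[mask, p - 1] / sd
            scale[col] = scale[col] * sd
    return replace(design, X=X, Z=Z, scale_factors=scale)


def back_transform(beta_standardized: np.ndarray, scale_factors: np.ndarray) -> np.ndarray:
    """Map coefficients from the standardized back to the original scale.

    With ``x* = x / s`` the linear predictor is invariant under
    ``beta = beta* / s``.
    """
    return np.asarray(beta_standardized, dtype=float) / np.asarray(scale_factors, dtype=float)


def read_long_format(path, chart: StateChart | None = None) -> pd.DataFrame:
    """Read a long-format CSV (columns id, trans, Tstart, Tstop, status, covariates)."""
    data = pd.read_csv(path)
    return validate_long_format(data, chart)


def write_long_format(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)
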