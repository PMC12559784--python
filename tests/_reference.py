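"""Independent brute-force reference implementations used as test oracles.

Everything here iterates over rows and risk sets naively, sharing no code
with the package's vectorized per-stratum accumulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp


def _risk_rows(df: pd.DataFrame, q: int, t: float) -> pd.DataFrame:
    """Rows of transition q at risk at event time t (left-truncated)."""
    return df[(df["trans"] == q) & (df["Tstart"] < t) & (t <= df["Tstop"])]


def naive_negloglik(df: pd.DataFrame, covs: list[str], beta_mat: np.ndarray) -> float:
    """Breslow-ties negative log partial likelihood by direct enumeration."""
    total = 0.0
    for _, row in df[df["status"] == 1].iterrows():
        q = int(row["trans"])
        risk = _risk_rows(df, q, float(row["Tstop"]))
        eta = risk[covs].to_numpy() @ beta_mat[:, q - 1]
        eta_i = np.asarray(row[covs], dtype=float) @ beta_mat[:, q - 1]
        total += -eta_i + logsumexp(eta)
    return total


def naive_score(df: pd.DataFrame, covs: list[str], beta_mat: np.ndarray) -> np.ndarray:
    """Score of log l as sum over events of (x_i - risk-set weighted mean)."""
    P, Q = beta_mat.shape
    U = np.zeros((P, Q))
    for _, row in df[df["status"] == 1].iterrows():
        q = int(row["trans"])
        risk = _risk_rows(df, q, float(row["Tstop"]))
        Z = risk[covs].to_numpy()
        w = np.exp(Z @ beta_mat[:, q - 1])
        zbar = (w @ Z) / w.sum()
        U[:, q - 1] += np.asarray(row[covs], dtype=float) - zbar
    return U.reshape(-1)  # covariate-major stacking


def naive_breslow(df: pd.DataFrame, covs: list[str], beta_mat: np.ndarray, q: int):
    """Breslow cumulative baseline hazard of one transition."""
    events = np.sort(df[(df["trans"] == q) & (df["status"] == 1)]["Tstop"].unique())
    cum = []
    total = 0.0
    for t in events:
        d = int(((df["trans"] == q) & (df["status"] == 1) & (df["Tstop"] == t)).sum())
        risk = _risk_rows(df, q, float(t))
        w = np.exp(risk[covs].to_numpy() @ beta_mat[:, q - 1])
        total += d / w.sum()
        cum.append(total)
    return events, np.array(cum)


def random_long_table(rng: np.random.Generator, n_subjects: int = 15, Q: int = 3,
                      P: int = 2, censor_frac: float = 0.4) -> pd.DataFrame:
    """Random small left-truncated long-format table for property tests."""
    rows = []
    for i in range(1, n_subjects + 1):
        x = rng.normal(size=P)
        for q in rng.permutation(Q)[: rng.integers(1, Q + 1)] + 1:
            start = rng.uniform(0, 1)
            stop = start + rng.uniform(0.05, 2.0)
            status = int(rng.uniform() > censor_frac)
            rows.append([i, int(q), start, stop, status, *x])
    df = pd.DataFrame(rows, columns=["id", "trans", "Tstart", "Tstop", "status",
                                     *[f"x{p}" for p in range(1, P + 1)]])
    if df["status"].sum() == 0:
        df.loc[df.index[0], "status"] = 1
    return df
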