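"""Performance measures for variable-selection simulation studies.

Selection quality is scored per replicate against the known truth by the
confusion counts over the PQ stacked coefficients, the true positive rate
TPR = TP / (TP + FN) and the false discovery rate FDR = FP / (TP + FP)
(defined as 0 when nothing is selected).  Estimation quality uses the
per-coefficient bias and the mean squared error over the d truly nonzero
coefficients only, MSEnz = (1/d) sum (beta_hat - beta)^2.  Monte-Carlo
standard errors follow the standard formulas for means and proportions,
and the replicate-count planning rule inverts the proportion MCSE.
"""

from __future__ import annotations

import math

import numpy as np


def confusion_counts(selected: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) of a selection mask against the true-nonzero mask."""
    selected = np.asarray(selected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if selected.shape != truth.shape:
        raise ValueError("selection and truth masks must have the same shape")
    tp = int(np.sum(selected & truth))
    fp = int(np.sum(selected & ~truth))
    tn = int(np.sum(~selected & ~truth))
    fn = int(np.sum(~selected & truth))
    return tp, fp, tn, fn


def tpr_fdr(counts: tuple[int, int, int, int]) -> tuple[float, float]:
    """True positive rate and false discovery rate from confusion counts.

    FDR is 0 by convention when no coefficient is selected.
    """
    tp, fp, _, fn = counts
    if tp + fn == 0:
        raise ValueError("truth mask has no nonzero coefficients")
    tpr = tp / (tp + fn)
    fdr = fp / (tp + fp) if (tp + fp) > 0 else 0.0
    return tpr, fdr


def bias_mse_nonzero(beta_hat: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-coefficient bias and MSE averaged over the truly nonzero ones."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if beta_hat.shape != truth.shape:
        raise ValueError("estimate and truth must have the same shape")
    nz = truth != 0.0
    d = int(nz.sum())
    if d == 0:
        raise ValueError("truth has no nonzero coefficients")
    bias = beta_hat - truth
    mse_nz = float(np.sum(bias[nz] ** 2) / d)
    return bias, mse_nz


def mcse(values: np.ndarray, statistic: str = "mean") -> float:
    """Monte-Carlo standard error of a simulation aggregate.

    ``"mean"``: sample SD / sqrt(nsim).  ``"proportion"``: values are 0/1
    (or probabilities averaged to p-hat), MCSE = sqrt(p(1-p)/nsim).
    """
    values = np.asarray(values, dtype=float)
    nsim = values.size
    if nsim < 2:
        raise ValueError("need at least two replicates")
    if statistic == "mean":
        return float(np.std(values, ddof=1) / math.sqrt(nsim))
    if statistic == "proportion":
        p = float(values.mean())
        return float(math.sqrt(p * (1.0 - p) / nsim))
    raise ValueError("statistic must be 'mean' or 'proportion'")


def required_nsim(target_tpr: float, target_mcse: float) -> int:
    """Replicates needed so MCSE of an anticipated proportion stays below target.

    nsim = ceil( p (1 - p) / mcse^2 ), e.g. 225 replicates for an
    anticipated TPR of 0.9 at MCSE 0.02.
    """
    if not (0.0 < target_tpr < 1.0):
        raise ValueError("target_tpr must be in (0, 1)")
    if target_mcse <= 0:
        raise ValueError("target_mcse must be positive")
    return math.ceil(target_tpr * (1.0 - target_tpr) / target_mcse**2)


def lower_median(values: np.ndarray) -> float:
    """Median with the lower-median convention for even counts.

    Returns an element of ``values``; for an even count the lower of the
    two middle order statistics is used (documented tie convention for
    reproducibility of reported medians).
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty input")
    return float(values[(values.size - 1) // 2])
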