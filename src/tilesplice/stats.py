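"""Shared statistical primitives: pooled two-sample t-tests and BH FDR."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["pooled_t_pvalues", "bh_adjust"]

# floor on the pooled variance so that groups with (near-)zero spread give
# p ≈ 0/1 when the means differ and exactly t = 0 (p = 0.5 one-sided, 1
# two-sided) when they coincide
VARIANCE_FLOOR = 1e-8


def pooled_t_pvalues(
    treatment: np.ndarray,
    control: np.ndarray,
    alternative: str = "two-sided",
    welch: bool = False,
) -> np.ndarray:
    """Row-wise two-sample t-test p-values (treatment vs control).

    ``treatment``/``control`` are 2-D (rows = features, columns = replicate
    arrays).  ``alternative``: "two-sided" or "greater" (treatment > control).
    Student (pooled-variance) by default; ``welch=True`` uses the
    Welch–Satterthwaite approximation.
    """
    t_arr = np.atleast_2d(np.asarray(treatment, dtype=float))
    c_arr = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n2 = t_arr.shape[1], c_arr.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per condition")
    diff = t_arr.mean(axis=1) - c_arr.mean(axis=1)
    v1 = t_arr.var(axis=1, ddof=1)
    v2 = c_arr.var(axis=1, ddof=1)
    if welch:
        se2 = np.maximum(v1 / n1 + v2 / n2, VARIANCE_FLOOR)
        df = se2**2 / np.maximum(
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1),
            np.finfo(float).tiny,
        )
        df = np.where((v1 + v2) > 0, df, n1 + n2 - 2)
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = np.maximum(pooled, VARIANCE_FLOOR) * (1 / n1 + 1 / n2)
        df = np.full_like(diff, n1 + n2 - 2)
    t_stat = diff / np.sqrt(se2)
    if alternative == "two-sided":
        p = 2 * sps.t.sf(np.abs(t_stat), df)
    elif alternative == "greater":
        p = sps.t.sf(t_stat, df)
    else:
        raise ValueError(f"unknown alternative: {alternative}")
    return p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
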