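"""Covariate adjustment: OLS residuals of a trait on age, sex and smoking,
standardized to unit variance — the trait actually fed into linkage.

The OLS step deliberately ignores relatedness (pooled across families);
residual familial correlation is what the variance-component stage models.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["AdjustmentError", "adjust", "adjust_replicates"]

COVARIATE_COLUMNS = ("age", "sex", "smoke")


class AdjustmentError(ValueError):
    """Degenerate adjustment problem (collinear covariates, zero residual variance)."""


def _design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise AdjustmentError(f"covariate table lacks columns: {missing}")
    cols = ["intercept"] + list(COVARIATE_COLUMNS)
    x = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )
    return x, cols


def adjust(trait: Sequence[float] | np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Standardized OLS residuals of ``trait`` on intercept + age + sex + smoking.

    Residuals are divided by their sample standard deviation (n-1
    denominator), so the output has mean ~0 and variance 1. Idempotent:
    adjusting an already-adjusted trait returns it unchanged.
    """
    y = np.asarray(trait, dtype=float)
    if y.ndim != 1 or len(y) != len(covariates):
        raise AdjustmentError("trait and covariate table lengths differ")
    if len(y) < 5:
        raise AdjustmentError(f"need at least 5 individuals, got {len(y)}")
    x, names = _design(covariates)

    # name the offending column on rank deficiency: QR diagonal collapses
    # at the first column linearly dependent on its predecessors
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    scale = np.linalg.norm(x, axis=0)
    bad = np.where(diag <= 1e-8 * np.maximum(scale, 1.0))[0]
    if bad.size:
        raise AdjustmentError(
            f"covariate {names[bad[0]]!r} is collinear with the preceding columns"
        )

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sd = resid.std(ddof=1)
    if sd <= 1e-12 * max(1.0, np.abs(y).max()):
        raise AdjustmentError("residual variance is zero; trait is determined by the covariates")
    return resid / sd


def adjust_replicates(replicates, traits: Sequence[str]) -> None:
    """Add a ``<trait>_adj`` standardized-residual column to each replicate's
    frame, adjusting per replicate over the pooled sample (all families)."""
    for rep in replicates:
        cov = rep.frame[list(COVARIATE_COLUMNS)]
        for t in traits:
            if t not in rep.frame.columns:
                raise AdjustmentError(f"replicate {rep.index}: trait {t!r} missing")
            rep.frame[f"{t}_adj"] = adjust(rep.frame[t].to_numpy(), cov)
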