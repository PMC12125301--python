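"""Shared correlation helper: Pearson r with OLS slope and two-sided p."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    pearson_r: float
    p_value: float
    n: int


def pearson_ols(x, y) -> CorrelationResult:
    """Pearson correlation with OLS slope, two-sided p-value.

    Raises ``ValueError`` on fewer than 3 pairs or zero variance on either
    axis (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and paired")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
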